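"""Seeded synthetic cohorts (remitters, non-remitters, controls) carrying the
statistical structure the downstream analysis assumes: band-limited latent
signals shared between seed and target regions at a planted per-subject
correlation, task-evoked responses, tissue nuisance signals, motion spikes
with matching intensity glitches, and a post-treatment session in which
non-remitter hypo-connectivity attenuates."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import BoldRun, IncompleteRecordError, SpecError, TaskDesign
from .geometry import center_in_grid, sphere_mask
from .residuals import condition_regressor

GROUPS = ("remitter", "nonremitter", "control")

DEFAULT_SEED_CENTERS = ((-11.0, -52.0, 37.0), (12.0, -52.0, 35.0))
DEFAULT_TARGET_CENTER = (-2.0, 50.0, -6.0)

#: columns every phenotype row must carry for a patient
REQUIRED_COVARIATES = (
    "age", "duration_mdd", "hrsd17_baseline", "hrsd17_week8", "drug", "dose_mg",
)


def default_grid(voxel_size_mm: float = 3.0,
                 seed_centers=DEFAULT_SEED_CENTERS,
                 target_center=DEFAULT_TARGET_CENTER,
                 pad_mm: float = 12.0):
    """Smallest axis-aligned grid whose voxel centers cover all region centers
    with ``pad_mm`` margin. Returns ``(shape, affine)`` with an isotropic
    RAS-aligned affine."""
    pts = np.array(list(seed_centers) + [tuple(target_center)], dtype=float)
    lo = pts.min(axis=0) - pad_mm
    hi = pts.max(axis=0) + pad_mm
    shape = tuple(int(np.ceil((h - l) / voxel_size_mm)) + 1 for l, h in zip(lo, hi))
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = lo
    return shape, affine


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    The planted effect lives in the mapping ``connectivity_by_group``: the
    seed-region and target-region latent signals of each subject are mixed at
    a per-subject correlation drawn around the group value (jitter applied on
    the Fisher-z scale with spread ``between_subject_z_sd``).
    """

    n_remit: int = 37
    n_nonremit: int = 38
    n_control: int = 31
    grid_shape: tuple | None = None
    voxel_size_mm: float = 3.0
    affine: np.ndarray | None = None
    n_runs: int = 5
    volumes_per_run: int = 120
    tr_s: float = 2.5
    n_sessions: int = 2
    seed_centers_mm: tuple = DEFAULT_SEED_CENTERS
    target_center_mm: tuple = DEFAULT_TARGET_CENTER
    seed_radius_mm: float = 5.0
    region_radius_mm: float = 6.0
    connectivity_by_group: dict = field(default_factory=lambda: {
        "control": 0.6, "remitter": 0.6, "nonremitter": 0.15,
    })
    post_shift_nonremit: float = 0.2
    between_subject_z_sd: float = 0.45
    within_region_z_sd: float = 0.0
    noise_sd: float = 0.5
    task_amplitude: float = 1.0
    tissue_amplitude: float = 1.0
    spike_rate: float = 2.0
    spike_amp_mm: float = 0.8
    spike_glitch: float = 40.0
    covariate_group_effects: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_remit, self.n_nonremit, self.n_control) < 0:
            raise SpecError("group sizes must be non-negative")
        if self.n_remit + self.n_nonremit + self.n_control == 0:
            raise SpecError("cohort is empty")
        for k in ("n_runs", "volumes_per_run", "n_sessions"):
            if getattr(self, k) <= 0:
                raise SpecError(f"{k} must be positive")
        for g, rho in self.connectivity_by_group.items():
            if abs(rho) >= 1:
                raise SpecError(f"|rho| must be < 1 for group {g!r} (got {rho})")
        if self.noise_sd < 0 or self.spike_amp_mm < 0 or self.spike_rate < 0:
            raise SpecError("noise/spike parameters must be non-negative")
        shape, affine = self.grid()
        for name, c in [("left seed", self.seed_centers_mm[0]),
                        ("right seed", self.seed_centers_mm[1]),
                        ("target", self.target_center_mm)]:
            if not center_in_grid(shape, affine, c):
                raise SpecError(f"{name} center {c} falls outside the grid")

    def grid(self):
        if self.grid_shape is not None and self.affine is not None:
            return tuple(self.grid_shape), np.asarray(self.affine, dtype=float)
        if self.grid_shape is not None or self.affine is not None:
            raise SpecError("grid_shape and affine must be given together")
        return default_grid(self.voxel_size_mm, self.seed_centers_mm,
                            self.target_center_mm)

    @property
    def n_subjects(self) -> int:
        return self.n_remit + self.n_nonremit + self.n_control

    def rho_for(self, group: str, session: int) -> float:
        rho = self.connectivity_by_group[group]
        if group == "nonremitter" and session >= 2:
            rho = float(np.tanh(np.arctanh(rho) + self.post_shift_nonremit))
        return rho


def planted_cohens_d(spec: CohortSpec) -> float:
    """Planted remitter-vs-non-remitter effect size of baseline target
    connectivity on the Fisher-z scale."""
    zr = np.arctanh(spec.connectivity_by_group["remitter"])
    zn = np.arctanh(spec.connectivity_by_group["nonremitter"])
    return float((zr - zn) / spec.between_subject_z_sd)


@dataclass
class SubjectGroundTruth:
    subject_id: str
    group: str
    rho_by_session: dict
    spike_frames: dict          # (session, run_index) -> tuple of frames
    age: float
    duration_mdd: float
    hrsd17_baseline: float
    hrsd17_week8: float
    drug: str                   # "" for controls
    dose_mg: float
    hrsd17_anxiety: float
    comorbid_anxiety: int
    early_life_stressors: int
    bmi: float
    cognitive_score: float


@dataclass
class SubjectDataset:
    subject_id: str
    group: str
    sessions: dict              # session number -> list[BoldRun]


def simulate_motion_trace(n_volumes: int, spike_rate: float,
                          spike_amp_mm: float, rng_seed):
    """Smooth sinusoidal drift plus step displacements at Bernoulli-thinned
    spike frames (per-frame probability ``spike_rate / n_volumes``).

    Returns ``(trace, spike_frames)`` with the trace as (n, 6): translations
    in mm, rotations in radians. Baseline (spike-free) framewise displacement
    stays well under 0.3 mm.
    """
    if n_volumes <= 0:
        raise SpecError("n_volumes must be positive")
    if spike_amp_mm < 0 or spike_rate < 0:
        raise SpecError("spike parameters must be non-negative")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    t = np.arange(n_volumes)
    trace = np.zeros((n_volumes, 6))
    for j in range(6):
        amp = rng.uniform(0.01, 0.04) if j < 3 else rng.uniform(2e-4, 8e-4)
        freq = rng.uniform(0.002, 0.01)
        phase = rng.uniform(0, 2 * np.pi)
        # small estimation jitter keeps lagged regressors distinguishable
        jitter = (0.002 if j < 3 else 4e-5) * rng.standard_normal(n_volumes)
        trace[:, j] = amp * np.sin(2 * np.pi * freq * t + phase) + jitter
    p = min(spike_rate / n_volumes, 1.0) if n_volumes > 1 else 0.0
    hit = rng.random(n_volumes) < p
    hit[0] = False  # frame 0 has no predecessor, a step there is unobservable
    spike_frames = np.flatnonzero(hit)
    for f in spike_frames:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        trace[f:, 0] += sign * spike_amp_mm
    return trace, spike_frames


def _band_limited(rng: np.random.Generator, n: int, tr_s: float,
                  low_hz: float = 0.01, high_hz: float = 0.08,
                  size: int | None = None) -> np.ndarray:
    """Unit-variance signal(s) synthesized in the frequency domain with
    support restricted to [low_hz, high_hz]. ``size`` requests a (size, n)
    array of independent signals."""
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    if not keep.any():  # degenerate short run: keep the lowest nonzero bin
        keep = np.zeros_like(freqs, dtype=bool)
        keep[min(1, freqs.size - 1)] = True
    m = size if size is not None else 1
    spec = np.zeros((m, freqs.size), dtype=complex)
    k = int(keep.sum())
    spec[:, keep] = rng.standard_normal((m, k)) + 1j * rng.standard_normal((m, k))
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    x = x / sd
    return x if size is not None else x[0]


def _default_task(run_index: int, n_volumes: int, tr_s: float) -> TaskDesign:
    duration = n_volumes * tr_s
    onsets = np.arange(12.5, duration - 10.0, 30.0)
    return TaskDesign(
        run_id=f"task{run_index + 1}",
        conditions=tuple(("stim", float(o), 10.0) for o in onsets),
    )


def region_masks(spec: CohortSpec) -> dict:
    """Boolean masks for the bilateral seed union and the planted target."""
    shape, affine = spec.grid()
    seed = np.zeros(shape, dtype=bool)
    for c in spec.seed_centers_mm:
        seed |= sphere_mask(shape, affine, c, spec.seed_radius_mm)
    target = sphere_mask(shape, affine, spec.target_center_mm,
                         spec.region_radius_mm)
    return {"seed": seed, "target": target}


def _draw_phenotype(rng: np.random.Generator, group: str,
                    group_effects: bool = True) -> dict:
    """Covariates with realistic group structure (non-remitters older, longer
    illness). With ``group_effects=False`` patient covariates come from the
    pooled distribution, decoupling them from outcome."""
    if group == "control":
        age, dur = rng.normal(29.93, 10.91), np.nan
    elif not group_effects:
        age, dur = rng.normal(31.70, 11.38), rng.normal(11.50, 10.88)
    elif group == "remitter":
        age, dur = rng.normal(28.34, 7.10), rng.normal(8.32, 6.48)
    else:
        age, dur = rng.normal(34.98, 13.69), rng.normal(14.61, 13.26)
    age = float(np.clip(age, 18, 70))
    if group == "control":
        base = float(np.clip(rng.normal(1.1, 1.3), 0, 7))
        week8 = float(np.clip(rng.normal(1.1, 1.3), 0, 7))
        drug, dose = "", np.nan
        anx = float(np.clip(rng.normal(0.45, 0.63), 0, None))
        els = int(rng.poisson(0.9))
        comorbid = 0
    else:
        dur = float(np.clip(dur, 0.3, 50))
        base = float(np.clip(np.round(rng.normal(21.1, 3.9)), 16, 34))
        if group == "remitter":
            week8 = float(rng.integers(0, 8))
        else:
            week8 = float(rng.integers(8, 21))
        drug = ("escitalopram", "sertraline", "venlafaxine")[int(rng.integers(3))]
        dose = {"escitalopram": rng.uniform(5, 20),
                "sertraline": rng.uniform(25, 100),
                "venlafaxine": rng.uniform(37.5, 150)}[drug]
        anx = float(np.clip(rng.normal(6.9, 2.0), 0, None))
        els = int(rng.poisson(3.8))
        comorbid = int(rng.random() < 0.47)
    return dict(
        age=age,
        duration_mdd=float(dur) if not np.isnan(dur) else np.nan,
        hrsd17_baseline=base,
        hrsd17_week8=week8,
        drug=drug,
        dose_mg=float(dose) if not np.isnan(dose) else np.nan,
        hrsd17_anxiety=anx,
        comorbid_anxiety=comorbid,
        early_life_stressors=els,
        bmi=float(np.clip(rng.normal(25.8, 5.6), 16, 45)),
        cognitive_score=float(rng.normal(0.0, 1.0)),
    )


def _subject_groups(spec: CohortSpec):
    return (["remitter"] * spec.n_remit
            + ["nonremitter"] * spec.n_nonremit
            + ["control"] * spec.n_control)


def iter_cohort(spec: CohortSpec, sessions_only=None, keep_data: bool = True):
    """Yield ``(SubjectDataset, SubjectGroundTruth)`` pairs.

    Deterministic given ``spec.rng_seed``: each subject draws from its own
    spawned bit stream, so the output is independent of consumption order.
    ``sessions_only`` restricts which sessions get BOLD data (ground truth
    still covers all sessions).
    """
    shape, affine = spec.grid()
    masks = region_masks(spec)
    seed_idx = np.flatnonzero(masks["seed"].ravel())
    target_idx = np.flatnonzero(masks["target"].ravel())
    n_vox = int(np.prod(shape))
    groups = _subject_groups(spec)
    children = np.random.SeedSequence(spec.rng_seed).spawn(len(groups) + 1)
    sessions = tuple(sessions_only) if sessions_only is not None \
        else tuple(range(1, spec.n_sessions + 1))

    # subject-level connectivity jitters, standardized within each group so
    # the planted effect size is exact at cohort level (not a noisy draw)
    jitter_rng = np.random.default_rng(children[-1])
    raw = jitter_rng.standard_normal(len(groups))
    jitters = np.empty(len(groups))
    garr = np.asarray(groups)
    for g in set(groups):
        m = garr == g
        block = raw[m]
        if block.size >= 2 and block.std() > 0:
            block = (block - block.mean()) / block.std()
        jitters[m] = block * spec.between_subject_z_sd

    for i, (group, child) in enumerate(zip(groups, children[:-1])):
        rng = np.random.default_rng(child)
        sid = f"sub-{i + 1:03d}"
        pheno = _draw_phenotype(rng, group, spec.covariate_group_effects)
        z_jitter = jitters[i]
        rho_by_session = {
            s: float(np.tanh(np.arctanh(spec.rho_for(group, s)) + z_jitter))
            for s in range(1, spec.n_sessions + 1)
        }
        # voxel-level subject trait: spatial heterogeneity of the planted
        # connectivity within the target region (drawn once per subject)
        voxel_dz = (rng.normal(0.0, spec.within_region_z_sd, target_idx.size)
                    if spec.within_region_z_sd > 0 else None)
        spike_truth = {}
        ses_runs = {}
        for s in sessions:
            runs = []
            for r in range(spec.n_runs):
                run, spikes = _generate_run(
                    rng, spec, shape, affine, n_vox, seed_idx, target_idx,
                    rho_by_session[s], r, voxel_dz=voxel_dz,
                )
                spike_truth[(s, r)] = tuple(int(f) for f in spikes)
                if keep_data:
                    runs.append(run)
            ses_runs[s] = runs
        truth = SubjectGroundTruth(
            subject_id=sid, group=group, rho_by_session=rho_by_session,
            spike_frames=spike_truth, **pheno,
        )
        yield SubjectDataset(subject_id=sid, group=group, sessions=ses_runs), truth


def _generate_run(rng, spec, shape, affine, n_vox, seed_idx, target_idx,
                  rho, run_index, voxel_dz=None):
    n = spec.volumes_per_run
    motion, spikes = simulate_motion_trace(n, spec.spike_rate,
                                           spec.spike_amp_mm, rng)
    s = _band_limited(rng, n, spec.tr_s)
    if voxel_dz is None:
        u = _band_limited(rng, n, spec.tr_s)[None, :]
        rho_v = rho
    else:
        u = _band_limited(rng, n, spec.tr_s, size=target_idx.size)
        rho_v = np.tanh(np.arctanh(rho) + voxel_dz)[:, None]
    # orthogonalize u against s in sample space and renormalize, so the
    # planted seed-target correlation holds exactly in the generated series
    u = u - np.outer(u @ s, s) / (s @ s)
    sd = u.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    u = u / sd
    if voxel_dz is None:
        u = u[0]
    wm = _band_limited(rng, n, spec.tr_s, low_hz=0.005, high_hz=0.05)
    vent = _band_limited(rng, n, spec.tr_s, low_hz=0.005, high_hz=0.05)
    task = _default_task(run_index, n, spec.tr_s)
    events = [(o, d) for _, o, d in task.conditions]
    task_sig = (condition_regressor(events, n, spec.tr_s) * spec.task_amplitude
                if events and spec.task_amplitude != 0 else np.zeros(n))

    data = rng.standard_normal((n_vox, n)) * spec.noise_sd + 100.0
    data[seed_idx] += s
    data[target_idx] += rho_v * s + np.sqrt(1.0 - np.square(rho_v)) * u
    task_gain = rng.uniform(0.5, 1.5, n_vox)
    data += np.outer(task_gain, task_sig)
    wm_gain = rng.normal(0.5, 0.2, n_vox)
    vent_gain = rng.normal(0.5, 0.2, n_vox)
    data += spec.tissue_amplitude * (np.outer(wm_gain, wm)
                                     + np.outer(vent_gain, vent))
    if spikes.size and spec.spike_glitch:
        data[:, spikes] += spec.spike_glitch

    run = BoldRun(
        run_id=task.run_id,
        data=data.reshape(*shape, n),
        affine=affine,
        tr_s=spec.tr_s,
        task=task,
        motion=motion,
        tissue_signals=np.column_stack([wm, vent]),
    )
    return run, spikes


def generate_cohort(spec: CohortSpec, sessions_only=None):
    """Materialize the whole cohort. Returns ``(subjects, truths)``; prefer
    :func:`iter_cohort` for large specs."""
    subjects, truths = [], []
    for subject, truth in iter_cohort(spec, sessions_only=sessions_only):
        subjects.append(subject)
        truths.append(truth)
    return subjects, truths


def make_phenotype_table(truths) -> pd.DataFrame:
    """One row per subject; raises if a patient record is missing a required
    covariate."""
    rows = []
    for t in truths:
        row = {
            "subject_id": t.subject_id, "group": t.group,
            "remitter": int(t.group == "remitter") if t.group != "control" else np.nan,
            "age": t.age, "duration_mdd": t.duration_mdd,
            "hrsd17_baseline": t.hrsd17_baseline, "hrsd17_week8": t.hrsd17_week8,
            "drug": t.drug, "dose_mg": t.dose_mg,
            "hrsd17_anxiety": t.hrsd17_anxiety,
            "comorbid_anxiety": t.comorbid_anxiety,
            "early_life_stressors": t.early_life_stressors,
            "bmi": t.bmi, "cognitive_score": t.cognitive_score,
        }
        if t.group != "control":
            for key in REQUIRED_COVARIATES:
                v = row[key]
                if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
                    raise IncompleteRecordError(
                        f"{t.subject_id}: missing covariate {key!r}")
        rows.append(row)
    return pd.DataFrame(rows)
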