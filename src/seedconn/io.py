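"""Dataset layout, readers/writers, and pipeline configuration.

Layout (BIDS-like, tool-agnostic)::

    <root>/participants.csv
    <root>/truth.json
    <root>/dataset.json
    <root>/masks/seed_union.nii.gz, target_region.nii.gz
    <root>/<subject>/ses-<n>/func/task-<name>_bold.nii.gz
                              task-<name>_motion.txt
                              task-<name>_tissue.tsv
                              task-<name>_events.tsv
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .connectivity import SeedSpec, ZMap
from .core import BoldRun, DataError, LoadError, TaskDesign
from .group import GroupModelSpec, PermutationConfig
from .qc import CensoringConfig
from .residuals import FilterBand


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline, serializable to YAML."""

    censoring: CensoringConfig = field(default_factory=CensoringConfig)
    band: FilterBand = field(default_factory=FilterBand)
    seed: SeedSpec = field(default_factory=SeedSpec)
    model: GroupModelSpec = field(default_factory=GroupModelSpec)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    roi_center_mm: tuple = (-2.0, 50.0, -6.0)
    roi_radius_mm: float = 10.0
    threshold_rule: str = "youden"
    loocv_threshold_rule: str = "fixed-0.5"
    rng_seed: int = 0
    task_order: tuple | None = None

    def to_dict(self) -> dict:
        def conv(v):
            if dataclasses.is_dataclass(v):
                return {k: conv(getattr(v, k))
                        for k in (f.name for f in dataclasses.fields(v))}
            if isinstance(v, (tuple, list)):
                return [conv(x) for x in v]
            if isinstance(v, np.generic):
                return v.item()
            return v
        return conv(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        sub = {"censoring": CensoringConfig, "band": FilterBand,
               "seed": SeedSpec, "model": GroupModelSpec,
               "permutation": PermutationConfig}
        for key, klass in sub.items():
            if key in d:
                payload = d.pop(key)
                if key == "seed" and "centers_mm" in payload:
                    payload["centers_mm"] = tuple(
                        tuple(c) for c in payload["centers_mm"])
                if key == "model" and "covariates" in payload:
                    payload["covariates"] = tuple(payload["covariates"])
                kwargs[key] = klass(**payload)
        for key in list(d):
            if key in {f.name for f in dataclasses.fields(cls)}:
                v = d.pop(key)
                if key in ("roi_center_mm", "task_order") and isinstance(v, list):
                    v = tuple(v)
                kwargs[key] = v
        if d:
            raise DataError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# NIfTI / text primitives
# ---------------------------------------------------------------------------

def save_nifti(path, data: np.ndarray, affine: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_motion_trace(path, trace: np.ndarray) -> None:
    np.savetxt(path, np.asarray(trace, dtype=float), fmt="%.8f")


def load_motion_trace(path) -> np.ndarray:
    trace = np.loadtxt(path, ndmin=2)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise LoadError(f"{path}: expected 6 columns, got shape {trace.shape}")
    return trace


# ---------------------------------------------------------------------------
# subject-level dataset
# ---------------------------------------------------------------------------

def _func_dir(root, subject_id, session) -> Path:
    return Path(root) / subject_id / f"ses-{session}" / "func"


def save_bold_run(root, subject_id, session, run: BoldRun) -> None:
    d = _func_dir(root, subject_id, session)
    d.mkdir(parents=True, exist_ok=True)
    stem = f"task-{run.run_id}"
    save_nifti(d / f"{stem}_bold.nii.gz", run.data, run.affine)
    save_motion_trace(d / f"{stem}_motion.txt", run.motion)
    pd.DataFrame(run.tissue_signals, columns=["wm", "ventricle"]).to_csv(
        d / f"{stem}_tissue.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"condition": c, "onset": o, "duration": dur}
         for c, o, dur in run.task.conditions]
    ).to_csv(d / f"{stem}_events.tsv", sep="\t", index=False)


def load_subject_dataset(root, subject_id, session=1, tr_s=None):
    """Load and validate all runs of one subject session.

    Checks run/trace/tissue lengths and affine consistency; failures name the
    offending file.
    """
    root = Path(root)
    meta = json.loads((root / "dataset.json").read_text())
    tr = tr_s if tr_s is not None else float(meta["tr_s"])
    d = _func_dir(root, subject_id, session)
    if not d.is_dir():
        raise LoadError(f"no session directory {d}")
    bold_files = sorted(d.glob("task-*_bold.nii.gz")) or sorted(
        d.glob("task-*_bold.nii"))
    if not bold_files:
        raise LoadError(f"no BOLD runs under {d}")
    runs, ref_affine = [], None
    for bf in bold_files:
        stem = bf.name.split("_bold")[0]
        data, affine = load_nifti(bf)
        if data.ndim != 4:
            raise LoadError(f"{bf}: expected 4D image")
        if ref_affine is None:
            ref_affine = affine
        elif not np.allclose(affine, ref_affine, atol=1e-5):
            raise DataError(f"{bf}: affine differs from other runs")
        motion_path = d / f"{stem}_motion.txt"
        if not motion_path.exists():
            raise LoadError(f"missing realignment trace {motion_path}")
        motion = load_motion_trace(motion_path)
        if motion.shape[0] != data.shape[3]:
            raise LoadError(
                f"{motion_path}: {motion.shape[0]} rows for "
                f"{data.shape[3]} volumes")
        tissue_path = d / f"{stem}_tissue.tsv"
        tissue = pd.read_csv(tissue_path, sep="\t").to_numpy(dtype=float) \
            if tissue_path.exists() else None
        if tissue is not None and tissue.shape[0] != data.shape[3]:
            raise LoadError(f"{tissue_path}: length mismatch")
        events_path = d / f"{stem}_events.tsv"
        conditions = ()
        if events_path.exists():
            ev = pd.read_csv(events_path, sep="\t")
            if len(ev):
                conditions = tuple(
                    (str(r.condition), float(r.onset), float(r.duration))
                    for r in ev.itertuples())
        runs.append(BoldRun(
            run_id=stem.replace("task-", ""), data=data, affine=affine,
            tr_s=tr, task=TaskDesign(stem.replace("task-", ""), conditions),
            motion=motion, tissue_signals=tissue))
    order = meta.get("task_order")
    if order:
        by_id = {r.run_id: r for r in runs}
        missing = [t for t in order if t not in by_id]
        if missing:
            raise LoadError(f"{subject_id} ses-{session}: missing runs {missing}")
        runs = [by_id[t] for t in order]
    return runs


def load_phenotype(root) -> pd.DataFrame:
    path = Path(root) / "participants.csv"
    if not path.exists():
        raise LoadError(f"missing phenotype table {path}")
    return pd.read_csv(path)


def write_cohort(root, spec, sessions_only=None) -> dict:
    """Materialize a synthetic cohort on disk in the documented layout."""
    from . import synthetic

    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    shape, affine = spec.grid()
    masks = synthetic.region_masks(spec)
    save_nifti(root / "masks" / "seed_union.nii.gz", masks["seed"], affine)
    save_nifti(root / "masks" / "target_region.nii.gz", masks["target"], affine)
    truths = []
    sessions = tuple(sessions_only) if sessions_only is not None else \
        tuple(range(1, spec.n_sessions + 1))
    task_order = None
    for subject, truth in synthetic.iter_cohort(spec, sessions_only=sessions):
        truths.append(truth)
        for ses, runs in subject.sessions.items():
            if task_order is None and runs:
                task_order = [r.run_id for r in runs]
            for run in runs:
                save_bold_run(root, subject.subject_id, ses, run)
    table = synthetic.make_phenotype_table(truths)
    table.to_csv(root / "participants.csv", index=False)
    (root / "dataset.json").write_text(json.dumps({
        "tr_s": spec.tr_s,
        "n_runs": spec.n_runs,
        "volumes_per_run": spec.volumes_per_run,
        "sessions": list(sessions),
        "grid_shape": list(shape),
        "task_order": task_order,
        "rng_seed": spec.rng_seed,
    }, indent=2))
    (root / "truth.json").write_text(json.dumps({
        t.subject_id: {
            "group": t.group,
            "rho_by_session": t.rho_by_session,
            "spike_frames": {f"{s}:{r}": list(v)
                             for (s, r), v in t.spike_frames.items()},
        } for t in truths
    }, indent=2))
    return {"root": str(root), "n_subjects": len(truths),
            "sessions": list(sessions)}


def write_zmap(root_out, zmap: ZMap, affine: np.ndarray) -> Path:
    path = Path(root_out) / "zmaps" / \
        f"{zmap.subject_id}_ses-{zmap.session}_zmap.nii.gz"
    save_nifti(path, zmap.data, affine)
    return path


def read_zmap(path, subject_id="", session=1) -> ZMap:
    data, _ = load_nifti(path)
    return ZMap(data=data, subject_id=subject_id, session=session,
                n_retained=0)


def write_censoring_report(out_dir, subject_id, results, excluded, total) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for run_idx, r in enumerate(results):
        for t in range(r.n_volumes):
            rows.append({
                "run": run_idx, "frame": t,
                "fd": r.fd_trace[t], "intensity": r.intensity_trace[t],
                "censored": bool(r.censored_mask[t]),
            })
    pd.DataFrame(rows).to_csv(out_dir / f"{subject_id}_censoring.tsv",
                              sep="\t", index=False)
    summary_path = out_dir / f"{subject_id}_censoring.json"
    summary_path.write_text(json.dumps({
        "subject_id": subject_id,
        "n_censored": int(total),
        "excluded": bool(excluded),
        "per_run_censored": [r.n_censored for r in results],
    }, indent=2))
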