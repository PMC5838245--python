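"""Per-run nuisance modeling of task BOLD: design matrices (task, 24-column
motion expansion, tissue, spike and baseline blocks), OLS residuals, band-pass
filtering, and concatenation into the intrinsic time course."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import BoldRun, DataError, TaskDesign
from .qc import CensoringResult


@dataclass(frozen=True)
class FilterBand:
    low_hz: float = 0.009
    high_hz: float = 0.08

    def validate(self, tr_s: float) -> None:
        nyquist = 1.0 / (2.0 * tr_s)
        if not (0 < self.low_hz < self.high_hz < nyquist):
            raise DataError(
                f"band ({self.low_hz}, {self.high_hz}) Hz must satisfy "
                f"0 < low < high < Nyquist ({nyquist:.4f} Hz)"
            )


@dataclass
class DesignMatrix:
    """Run design matrix with labeled column blocks.

    ``blocks`` maps block names ({'task', 'motion24', 'tissue', 'spike',
    'baseline'}) to column index arrays.
    """

    matrix: np.ndarray
    labels: list
    blocks: dict

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ResidualSeries:
    """Voxels-by-time residual series with carried censoring mask.

    ``data`` is (n_voxels, n_volumes) in flattened C order over the 3D grid.
    """

    data: np.ndarray
    shape3d: tuple
    affine: np.ndarray
    censored: np.ndarray
    run_lengths: list

    def __post_init__(self):
        if self.data.shape[1] != self.censored.size:
            raise DataError("censored mask length must match volume count")
        if sum(self.run_lengths) != self.data.shape[1]:
            raise DataError("run boundary lengths do not sum to volume count")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    @property
    def retained_frames(self) -> np.ndarray:
        return np.flatnonzero(~self.censored)


def canonical_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Double-gamma hemodynamic response sampled at the TR (peak 6 s,
    undershoot 16 s, peak/undershoot ratio 6), normalized to unit peak."""
    t = np.arange(0, duration_s + tr_s / 2, tr_s)
    from scipy.stats import gamma as gamma_dist

    h = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6.0
    peak = np.max(np.abs(h))
    if peak == 0:
        raise DataError("degenerate HRF sampling")
    return h / peak


def condition_regressor(onsets_durations, n_volumes: int, tr_s: float) -> np.ndarray:
    """HRF-convolved boxcar for one condition, sampled at volume times."""
    box = np.zeros(n_volumes)
    times = np.arange(n_volumes) * tr_s
    for onset, dur in onsets_durations:
        box[(times >= onset) & (times < onset + max(dur, tr_s / 2))] = 1.0
    hrf = canonical_hrf(tr_s)
    return np.convolve(box, hrf)[:n_volumes]


def motion24(trace: np.ndarray) -> np.ndarray:
    """Volterra expansion of the 6 realignment parameters: current values,
    their squares, one-frame lags, and squared lags (24 columns). Lagged
    columns are 0 at the first frame."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise DataError(f"realignment trace must be (n, 6), got {trace.shape}")
    lag = np.vstack([np.zeros((1, 6)), trace[:-1]])
    return np.hstack([trace, trace**2, lag, lag**2])


def build_design_matrix(
    task: TaskDesign,
    trace: np.ndarray,
    tissue_signals: np.ndarray,
    censoring: CensoringResult,
    tr_s: float,
    n_volumes: int | None = None,
) -> DesignMatrix:
    """Assemble the per-run design: HRF-convolved condition regressors, the
    24-column motion expansion, 2 demeaned tissue signals, one indicator per
    censored frame, and an intercept + linear drift baseline."""
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[0] if n_volumes is None else int(n_volumes)
    tissue = np.asarray(tissue_signals, dtype=float)
    if trace.shape[0] != n:
        raise DataError("realignment trace length does not match volume count")
    if tissue.shape != (n, 2):
        raise DataError(f"tissue signals must be ({n}, 2), got {tissue.shape}")
    if censoring.n_volumes != n:
        raise DataError("censoring mask length does not match volume count")
    task.validate(n * tr_s)

    cols, labels, blocks = [], [], {}

    def add_block(name, block, block_labels):
        start = sum(c.shape[1] for c in cols)
        blocks[name] = np.arange(start, start + block.shape[1])
        cols.append(block)
        labels.extend(block_labels)

    events_by_cond = {}
    for cname, onset, dur in task.conditions:
        events_by_cond.setdefault(cname, []).append((onset, dur))
    task_cols = [
        condition_regressor(events_by_cond[c], n, tr_s)
        for c in sorted(events_by_cond)
    ]
    add_block(
        "task",
        np.column_stack(task_cols) if task_cols else np.empty((n, 0)),
        [f"task_{c}" for c in sorted(events_by_cond)],
    )

    m24 = motion24(trace)
    m24_labels = (
        [f"mot_{i}" for i in range(6)]
        + [f"mot_{i}_sq" for i in range(6)]
        + [f"mot_{i}_lag" for i in range(6)]
        + [f"mot_{i}_lag_sq" for i in range(6)]
    )
    add_block("motion24", m24, m24_labels)

    add_block("tissue", tissue - tissue.mean(axis=0), ["wm", "ventricle"])

    add_block(
        "spike",
        censoring.spike_regressors,
        [f"spike_{t}" for t in np.flatnonzero(censoring.censored_mask)],
    )

    drift = np.linspace(-1.0, 1.0, n)
    add_block("baseline", np.column_stack([np.ones(n), drift]), ["intercept", "drift"])

    return DesignMatrix(matrix=np.hstack(cols), labels=labels, blocks=blocks)


def fit_glm_residuals(run, design: DesignMatrix, censoring=None) -> np.ndarray:
    """OLS residuals per voxel, rank deficiency handled by pseudoinverse.

    ``run`` may be a BoldRun or a (n_voxels, n_volumes) array. Returns a
    (n_voxels, n_volumes) residual array; censored frames (absorbed by their
    indicator columns) come out exactly 0 up to floating point.
    """
    if isinstance(run, BoldRun):
        data = run.data.reshape(-1, run.n_volumes)
    else:
        data = np.asarray(run, dtype=float)
    if not np.all(np.isfinite(data)):
        raise DataError("non-finite voxel series")
    X = design.matrix
    if X.shape[0] != data.shape[1]:
        raise DataError("design rows do not match run volumes")
    # project onto the orthogonal complement of the design column space via
    # SVD: column-normalize first (raw motion-squared columns, radians^2, are
    # ~1e-7 in norm), then drop numerically null directions; residuals stay
    # orthogonal to every column even for rank-deficient designs
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    U, s, _ = np.linalg.svd(X / norms, full_matrices=False)
    U = U[:, s > s[0] * 1e-12]
    resid = data - (data @ U) @ U.T
    if censoring is not None:
        resid[:, censoring.censored_mask] = 0.0
    return resid


def bandpass_filter(
    data: np.ndarray,
    band: FilterBand,
    tr_s: float,
    run_lengths=None,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass applied independently per run segment.

    ``data`` is (n_voxels, n_volumes); ``run_lengths`` defaults to one segment.
    """
    band.validate(tr_s)
    data = np.asarray(data, dtype=float)
    fs = 1.0 / tr_s
    sos = signal.butter(order, [band.low_hz, band.high_hz], btype="bandpass",
                        fs=fs, output="sos")
    if run_lengths is None:
        run_lengths = [data.shape[1]]
    if sum(run_lengths) != data.shape[1]:
        raise DataError("run lengths do not sum to volume count")
    out = np.empty_like(data)
    start = 0
    for length in run_lengths:
        if length < 30:
            raise DataError(f"run of {length} volumes too short to filter (< 30)")
        seg = data[:, start:start + length]
        out[:, start:start + length] = signal.sosfiltfilt(sos, seg, axis=1)
        start += length
    return out


def filter_response(band: FilterBand, tr_s: float, freqs_hz, order: int = 4) -> np.ndarray:
    """Amplitude response of the zero-phase filter at the given frequencies
    (forward-backward pass squares the single-pass magnitude)."""
    fs = 1.0 / tr_s
    sos = signal.butter(order, [band.low_hz, band.high_hz], btype="bandpass",
                        fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs_hz) / fs)
    return np.abs(h) ** 2


def concatenate_runs(series_list) -> ResidualSeries:
    """Concatenate per-run residual series in the given (configured task)
    order, recording run boundaries and carrying censoring masks through."""
    if not series_list:
        raise DataError("no runs to concatenate")
    first = series_list[0]
    for s in series_list[1:]:
        if s.shape3d != first.shape3d or not np.allclose(s.affine, first.affine):
            raise DataError("run grids/affines do not match")
    return ResidualSeries(
        data=np.hstack([s.data for s in series_list]),
        shape3d=first.shape3d,
        affine=first.affine,
        censored=np.concatenate([s.censored for s in series_list]),
        run_lengths=[length for s in series_list for length in s.run_lengths],
    )


def run_to_residual_series(
    run: BoldRun,
    censoring: CensoringResult,
    band: FilterBand = FilterBand(),
) -> ResidualSeries:
    """One run through nuisance GLM + band-pass, as a ResidualSeries."""
    if run.tissue_signals is None:
        raise DataError(f"run {run.run_id!r} has no tissue signals")
    design = build_design_matrix(
        run.task, run.motion, run.tissue_signals, censoring, run.tr_s
    )
    resid = fit_glm_residuals(run, design, censoring)
    filtered = bandpass_filter(resid, band, run.tr_s)
    return ResidualSeries(
        data=filtered,
        shape3d=run.grid_shape,
        affine=run.affine,
        censored=censoring.censored_mask.copy(),
        run_lengths=[run.n_volumes],
    )
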