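"""Motion/intensity quality control: framewise displacement, scaled signal
change, temporal-mask construction, and the subject exclusion rule."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BoldRun, DataError


@dataclass(frozen=True)
class CensoringConfig:
    """Thresholds and window extents for volume censoring.

    Frames exceeding either threshold are spikes; each spike censors the
    window ``[t - mask_before, t + mask_after]`` (4 frames by default).
    A subject with more than ``max_censored_volumes`` censored across all
    runs is excluded from group analyses.
    """

    fd_threshold_mm: float = 0.3
    intensity_threshold: float = 10.0
    mask_before: int = 1
    mask_after: int = 2
    max_censored_volumes: int = 200
    rotation_radius_mm: float = 50.0

    def __post_init__(self):
        if self.fd_threshold_mm <= 0 or self.intensity_threshold <= 0:
            raise DataError("censoring thresholds must be positive")
        if self.mask_before < 0 or self.mask_after < 0:
            raise DataError("mask extents must be non-negative")
        if self.rotation_radius_mm <= 0:
            raise DataError("rotation radius must be positive")


@dataclass
class CensoringResult:
    """Per-run censoring diagnostics and temporal masks."""

    fd_trace: np.ndarray
    intensity_trace: np.ndarray
    spike_frames: np.ndarray
    censored_mask: np.ndarray
    spike_regressors: np.ndarray  # (n_volumes, n_censored), one column per frame

    @property
    def n_volumes(self) -> int:
        return self.censored_mask.size

    @property
    def n_censored(self) -> int:
        return int(self.censored_mask.sum())


def compute_fd(trace: np.ndarray, rotation_radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement: sum of absolute backward differences of the six
    realignment parameters, rotations converted to arc length at
    ``rotation_radius_mm``. The first frame has FD 0.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise DataError(f"realignment trace must be (n, 6), got {trace.shape}")
    if not np.all(np.isfinite(trace)):
        raise DataError("realignment trace contains non-finite values")
    scaled = trace.copy()
    scaled[:, 3:] *= rotation_radius_mm
    fd = np.zeros(trace.shape[0])
    fd[1:] = np.sum(np.abs(np.diff(scaled, axis=0)), axis=1)
    return fd


def compute_scaled_signal_change(run) -> np.ndarray:
    """Scaled signal intensity difference (DVARS-like): per volume, the mean
    over voxels of the squared intensity change from the previous volume,
    divided by the grand mean intensity over the full series. First frame 0.
    """
    data = run.data if isinstance(run, BoldRun) else np.asarray(run, dtype=float)
    if data.ndim != 4:
        raise DataError("expected 4D data")
    if data.shape[3] < 2:
        raise DataError("need at least 2 volumes")
    if not np.all(np.isfinite(data)):
        raise DataError("non-finite intensities")
    grand_mean = float(data.mean())
    if grand_mean == 0:
        raise DataError("zero grand-mean intensity; cannot scale signal change")
    flat = data.reshape(-1, data.shape[3])
    msd = np.mean(np.diff(flat, axis=1) ** 2, axis=0)
    out = np.zeros(data.shape[3])
    out[1:] = msd / grand_mean
    return out


def build_temporal_mask(
    fd_trace: np.ndarray,
    intensity_trace: np.ndarray,
    config: CensoringConfig = CensoringConfig(),
) -> CensoringResult:
    """Flag spike frames (FD >= threshold or intensity change > threshold) and
    censor a window around each: ``mask_before`` frames before through
    ``mask_after`` frames after, clipped to the run."""
    fd = np.asarray(fd_trace, dtype=float)
    intensity = np.asarray(intensity_trace, dtype=float)
    if fd.shape != intensity.shape or fd.ndim != 1:
        raise DataError("fd and intensity traces must be 1D and equal length")
    n = fd.size
    spikes = np.flatnonzero(
        (fd >= config.fd_threshold_mm) | (intensity > config.intensity_threshold)
    )
    censored = np.zeros(n, dtype=bool)
    for t in spikes:
        censored[max(0, t - config.mask_before): min(n, t + config.mask_after + 1)] = True
    idx = np.flatnonzero(censored)
    regressors = np.zeros((n, idx.size))
    regressors[idx, np.arange(idx.size)] = 1.0
    return CensoringResult(
        fd_trace=fd,
        intensity_trace=intensity,
        spike_frames=spikes,
        censored_mask=censored,
        spike_regressors=regressors,
    )


def censor_run(run: BoldRun, config: CensoringConfig = CensoringConfig()) -> CensoringResult:
    """Convenience wrapper: FD from the run's motion trace, intensity change
    from its data, then the temporal mask."""
    if run.motion is None:
        raise DataError(f"run {run.run_id!r} has no realignment trace")
    fd = compute_fd(run.motion, config.rotation_radius_mm)
    dvars = compute_scaled_signal_change(run)
    return build_temporal_mask(fd, dvars, config)


def apply_exclusion_rule(results, config: CensoringConfig = CensoringConfig()):
    """Subject-level decision: excluded iff the total censored-volume count
    across runs strictly exceeds ``max_censored_volumes``.

    Returns ``(excluded, total_censored)``.
    """
    if not results:
        raise DataError("no runs supplied for exclusion decision")
    total = int(sum(r.n_censored for r in results))
    return total > config.max_censored_volumes, total
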