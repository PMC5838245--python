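"""Bilateral seed extraction and per-subject voxel-wise Fisher-z maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DataError, GeometryError
from .geometry import sphere_mask
from .residuals import ResidualSeries

R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class SeedSpec:
    """Union-of-spheres seed in world coordinates."""

    centers_mm: tuple = ((-11.0, -52.0, 37.0), (12.0, -52.0, 35.0))
    radius_mm: float = 5.0

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise GeometryError("seed radius must be positive")
        if len(self.centers_mm) < 1:
            raise GeometryError("seed needs at least one center")

    def mask(self, shape, affine) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        for c in self.centers_mm:
            out |= sphere_mask(shape, affine, c, self.radius_mm)
        if not out.any():
            raise GeometryError("seed union mask is empty")
        return out


@dataclass
class SeedSeries:
    """Seed mean series restricted to retained (non-censored) frames."""

    values: np.ndarray
    frames: np.ndarray

    def __post_init__(self):
        if self.values.shape != self.frames.shape:
            raise DataError("values/frames length mismatch")


@dataclass
class ZMap:
    """Voxel-wise Fisher-z seed-connectivity map for one subject/session."""

    data: np.ndarray
    subject_id: str = ""
    session: int = 1
    seed: SeedSpec | None = None
    n_retained: int = 0
    zero_variance: np.ndarray | None = None  # QC flag per voxel

    def __post_init__(self):
        if not np.all(np.isfinite(self.data)):
            raise DataError("z map contains non-finite values")


def make_sphere_mask(center_mm, radius_mm, shape, affine) -> np.ndarray:
    """Single world-space sphere as a boolean voxel mask (membership by
    voxel-center distance)."""
    return sphere_mask(shape, affine, center_mm, radius_mm)


def extract_seed_series(series: ResidualSeries, seed: SeedSpec) -> SeedSeries:
    """Unweighted mean over the union of seed-sphere voxels, evaluated only at
    retained frames."""
    mask = seed.mask(series.shape3d, series.affine)
    frames = series.retained_frames
    values = series.data[mask.ravel()][:, frames].mean(axis=0)
    return SeedSeries(values=values, frames=frames)


def seed_zmap(series: ResidualSeries, seed_series: SeedSeries,
              subject_id: str = "", session: int = 1,
              seed: SeedSpec | None = None, min_frames: int = 30) -> ZMap:
    """Pearson correlation of every voxel with the seed over retained frames,
    Fisher-z transformed with |r| clipped to ``1 - 1e-7``. Zero-variance
    voxels get z = 0 and a QC flag."""
    frames = seed_series.frames
    if frames.size < min_frames:
        raise DataError(
            f"only {frames.size} retained frames (< {min_frames}) for z map")
    y = series.data[:, frames]
    s = seed_series.values
    s_c = s - s.mean()
    s_norm = np.sqrt(np.sum(s_c**2))
    if s_norm == 0:
        raise DataError("seed series has zero variance")
    y_c = y - y.mean(axis=1, keepdims=True)
    y_norm = np.sqrt(np.sum(y_c**2, axis=1))
    # relative tolerance: constant series leave float residue after demeaning
    zero_var = y_norm <= 1e-10 * (np.abs(y).max(axis=1) + 1.0)
    denom = np.where(zero_var, 1.0, y_norm) * s_norm
    r = (y_c @ s_c) / denom
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    z[zero_var] = 0.0
    return ZMap(
        data=z.reshape(series.shape3d),
        subject_id=subject_id,
        session=session,
        seed=seed,
        n_retained=int(frames.size),
        zero_variance=zero_var.reshape(series.shape3d),
    )
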