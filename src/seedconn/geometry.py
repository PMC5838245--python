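"""Voxel-grid geometry: world/voxel coordinate maps and spherical masks."""

from __future__ import annotations

import numpy as np

from .core import GeometryError


def world_to_voxel(affine: np.ndarray, xyz_mm) -> np.ndarray:
    """Map world (mm) coordinates to continuous voxel indices."""
    affine = np.asarray(affine, dtype=float)
    xyz = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
    inv = np.linalg.inv(affine)
    ijk = xyz @ inv[:3, :3].T + inv[:3, 3]
    return ijk[0] if np.ndim(xyz_mm) == 1 else ijk


def voxel_to_world(affine: np.ndarray, ijk) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    ijk_arr = np.atleast_2d(np.asarray(ijk, dtype=float))
    xyz = ijk_arr @ affine[:3, :3].T + affine[:3, 3]
    return xyz[0] if np.ndim(ijk) == 1 else xyz


def center_in_grid(shape, affine, center_mm) -> bool:
    ijk = world_to_voxel(affine, center_mm)
    return bool(np.all(ijk >= -0.5) and np.all(ijk <= np.asarray(shape) - 0.5))


def sphere_mask(shape, affine, center_mm, radius_mm: float) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within ``radius_mm`` of a
    world-space center.

    Raises
    ------
    GeometryError
        If the center falls outside the grid or the mask would be empty.
    """
    if radius_mm <= 0:
        raise GeometryError("sphere radius must be positive")
    if not center_in_grid(shape, affine, center_mm):
        raise GeometryError(
            f"sphere center {tuple(np.asarray(center_mm, float))} maps outside "
            f"grid of shape {tuple(shape)}"
        )
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
        indexing="ij",
    )
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    xyz = voxel_to_world(affine, ijk)
    d2 = np.sum((xyz - np.asarray(center_mm, dtype=float)) ** 2, axis=1)
    mask = (d2 <= radius_mm**2).reshape(shape)
    if not mask.any():
        raise GeometryError("sphere mask is empty at this radius/grid")
    return mask
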