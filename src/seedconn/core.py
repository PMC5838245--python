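"""Shared domain types and exceptions used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SeedconnError(Exception):
    """Base class for all package errors."""


class SpecError(SeedconnError):
    """Invalid generation or configuration parameters."""


class DataError(SeedconnError):
    """Malformed or inconsistent input data."""


class GeometryError(SeedconnError):
    """Region geometry does not intersect the voxel grid as required."""


class StatsError(SeedconnError):
    """Degenerate inputs to a statistical routine."""


class IncompleteRecordError(DataError):
    """A phenotype record is missing a required field."""


class LoadError(DataError):
    """A dataset file is missing or fails validation."""


@dataclass(frozen=True)
class TaskDesign:
    """Event timing for one task run.

    ``conditions`` is a list of ``(name, onset_s, duration_s)`` events.
    """

    run_id: str
    conditions: tuple = ()

    def condition_names(self):
        return sorted({name for name, _, _ in self.conditions})

    def validate(self, run_duration_s: float) -> None:
        for name, onset, dur in self.conditions:
            if dur < 0:
                raise DataError(f"negative duration for condition {name!r}")
            if not (0 <= onset < run_duration_s):
                raise DataError(
                    f"onset {onset} of condition {name!r} outside run "
                    f"duration {run_duration_s}"
                )


@dataclass
class BoldRun:
    """One 4D task run with its acquisition and nuisance side-channels.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz, n_volumes)
    affine : ndarray, shape (4, 4)
        Voxel-to-world map (RAS mm).
    tr_s : float
    task : TaskDesign
    motion : ndarray, shape (n_volumes, 6)
        Rigid-body realignment trace: 3 translations (mm), 3 rotations (rad).
    tissue_signals : ndarray, shape (n_volumes, 2) or None
        Mean white-matter and ventricle time courses.
    """

    run_id: str
    data: np.ndarray
    affine: np.ndarray
    tr_s: float
    task: TaskDesign = field(default_factory=lambda: TaskDesign("run"))
    motion: np.ndarray | None = None
    tissue_signals: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise DataError(f"BOLD data must be 4D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise DataError("affine must be 4x4")
        if self.tr_s <= 0:
            raise DataError("TR must be positive")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape != (self.n_volumes, 6):
                raise DataError(
                    f"motion trace shape {self.motion.shape} does not match "
                    f"{self.n_volumes} volumes"
                )
        if self.tissue_signals is not None:
            self.tissue_signals = np.asarray(self.tissue_signals, dtype=float)
            if self.tissue_signals.shape != (self.n_volumes, 2):
                raise DataError("tissue_signals must have shape (n_volumes, 2)")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]
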