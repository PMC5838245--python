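import numpy as np
import pytest

from seedconn.synthetic import CohortSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """Small, fast cohort: coarse grid, short runs."""
    return CohortSpec(
        n_remit=4, n_nonremit=4, n_control=3,
        n_runs=1, volumes_per_run=48, voxel_size_mm=6.0,
        n_sessions=1, spike_rate=0.5, rng_seed=7,
    )


def grid_on_voxel_centers(shape, voxel_size, center_index):
    """Affine placing world origin on the center of ``center_index``."""
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = -voxel_size * np.asarray(center_index, dtype=float)
    return affine
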