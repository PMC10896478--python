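import numpy as np
import pytest

from fcsconn.grid import MaskedVolumeGrid
from fcsconn.preproc import BoldSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_grid():
    """A 3x3x2 solid block at 3 mm (18 voxels)."""
    mask = np.zeros((5, 5, 4), dtype=bool)
    mask[1:4, 1:4, 1:3] = True
    return MaskedVolumeGrid(mask, 3.0)


@pytest.fixture
def elongated_grid():
    """A thin 40-voxel-long bar at 3 mm so distances span >100 mm."""
    mask = np.ones((40, 3, 3), dtype=bool)
    return MaskedVolumeGrid(mask, 3.0)


def random_series(grid, n_timepoints=64, seed=0):
    r = np.random.default_rng(seed)
    return BoldSeries(r.standard_normal((grid.n_voxels, n_timepoints)))


def random_mask_grid(seed, max_voxels=100, voxel_size=3.0):
    """Random connected-ish mask with at most max_voxels voxels."""
    r = np.random.default_rng(seed)
    shape = tuple(int(v) for v in r.integers(4, 8, size=3))
    mask = r.random(shape) < 0.6
    mask.flat[0] = True
    flat = np.flatnonzero(mask.ravel())
    if flat.size > max_voxels:
        keep = r.choice(flat, size=max_voxels, replace=False)
        mask = np.zeros(mask.size, dtype=bool)
        mask[keep] = True
        mask = mask.reshape(shape)
    if mask.sum() < 2:
        mask.flat[:3] = True
    return MaskedVolumeGrid(mask, voxel_size)
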