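import numpy as np
import pytest

from alffnet.grid import VolumeGrid


def centered_grid(shape=(15, 15, 15), voxel_mm=3.0, mask=None):
    """Grid whose world origin coincides with the central voxel's center."""
    shape = tuple(shape)
    affine = np.diag([voxel_mm] * 3 + [1.0])
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_mm
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    return VolumeGrid(shape=shape, affine=affine, brain_mask=mask)


@pytest.fixture
def grid3mm():
    return centered_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
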