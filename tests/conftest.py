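import numpy as np
import pytest

from mitometry.stack_io import VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_grid_2d():
    """A 2D two-channel grid with 1 µm² pixels for arithmetic checks."""
    data = np.zeros((2, 40, 40), dtype=float)
    return VoxelGrid(data, ("signal", "marker"), (1.0, 1.0))


def make_grid_2d(channels: dict, pixel_um=(1.0, 1.0)) -> VoxelGrid:
    names = tuple(channels)
    data = np.stack([np.asarray(channels[n], dtype=float) for n in names])
    return VoxelGrid(data, names, pixel_um)


def make_grid_3d(channels: dict, voxel_um=(0.3, 0.1, 0.1)) -> VoxelGrid:
    names = tuple(channels)
    data = np.stack([np.asarray(channels[n], dtype=float) for n in names])
    return VoxelGrid(data, names, voxel_um)
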