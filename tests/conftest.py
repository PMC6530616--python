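import numpy as np
import pytest

from mvctdose import VoxelGrid, make_cheese_phantom, synthesize_beam_model


@pytest.fixture(scope="session")
def model():
    """Default synthetic beam model, uncalibrated (1 cGy/MU sentinel)."""
    return synthesize_beam_model()


@pytest.fixture(scope="session")
def cheese_coarse():
    """30-cm cheese phantom at 0.5-cm voxels (fast unit-test resolution)."""
    return make_cheese_phantom(spacing=0.5)


@pytest.fixture(scope="session")
def water_cube():
    """20^3 homogeneous water cube, 0.5-cm voxels, centered at the origin."""
    dims = (20, 20, 20)
    spacing = np.full(3, 0.5)
    origin = -0.5 * spacing * np.asarray(dims)
    return VoxelGrid(origin, spacing, np.ones(dims))
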