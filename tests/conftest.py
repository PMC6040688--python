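import numpy as np
import pytest

from fractal3d import FDParams, VoxelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def solid_cube_16():
    return VoxelVolume(np.ones((16, 16, 16), dtype=bool))


@pytest.fixture
def fast_params():
    """Small-offset parameters for cheap estimator runs in unit tests."""
    return FDParams(n_offsets=5, offset_seed=7, min_fit_points=8)


def random_volume(rng, max_edge=12, p=0.4):
    """Small random volume guaranteed nonempty."""
    shape = tuple(rng.integers(3, max_edge + 1, size=3))
    occ = rng.random(shape) < p
    if not occ.any():
        occ[tuple(rng.integers(0, s) for s in shape)] = True
    return VoxelVolume(occ)
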