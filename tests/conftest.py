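import numpy as np
import pytest

from cryoenhance import (
    DensityMap,
    auto_grid_for_structure,
    gaussian_constants,
    make_toy_structure,
    simulate_map,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_map(rng):
    data = rng.random((10, 12, 14))
    return DensityMap(data, voxel_size=(1.0, 1.0, 1.0), origin=(1.5, -2.0, 3.0))


@pytest.fixture
def helix_structure():
    return make_toy_structure(10, "helix", np.random.default_rng(0))


@pytest.fixture
def helix_clean_map(helix_structure):
    grid = auto_grid_for_structure(helix_structure, voxel_size=1.0, padding=5.0)
    return simulate_map(helix_structure, gaussian_constants(4.0), grid)
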