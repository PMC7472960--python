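import numpy as np
import pytest

from lesionmap.grid import make_grid
from lesionmap.synthetic import build_region_atlas


@pytest.fixture(scope="session")
def grid():
    """The default MNI-like 4 mm analysis grid."""
    return make_grid((45, 54, 45), (4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def atlas(grid):
    return build_region_atlas(grid)


@pytest.fixture(scope="session")
def small_grid():
    """A tiny grid for brute-force map oracles."""
    return make_grid((5, 5, 5), (2.0, 2.0, 2.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
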