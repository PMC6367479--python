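import numpy as np
import pytest

from specloc.grids import make_elevation_grid, make_frequency_grid
from specloc.hrtf import default_hrtf_set
from specloc.pipeline import make_fixtures
from specloc.stimulus import make_stimulus_matrix


@pytest.fixture(scope="session")
def grid():
    return make_frequency_grid(0.5, 20.0, 64)


@pytest.fixture(scope="session")
def elevations():
    return make_elevation_grid()


@pytest.fixture(scope="session")
def hrtfs():
    """Canonical HRTF set on the default grids (59 elevations x 0.5-20 kHz)."""
    return default_hrtf_set()


@pytest.fixture(scope="session")
def stimulus_matrix(grid):
    return make_stimulus_matrix(grid)


@pytest.fixture(scope="session")
def mini():
    """Miniature deterministic bundle: coarse grid, 5 elevations, 3 stimuli."""
    return make_fixtures(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
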