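import numpy as np
import pytest

from restoreplan.grids import GridSpec
from restoreplan.synthetic import SyntheticConfig, generate_landscape, sample_plots


@pytest.fixture(scope="session")
def grid200():
    return GridSpec(200, 200)


@pytest.fixture(scope="session")
def default_stack(grid200):
    """One default-condition landscape shared across read-only tests."""
    return generate_landscape(SyntheticConfig(seed=11), grid200)


@pytest.fixture(scope="session")
def default_plots(default_stack):
    return sample_plots(default_stack, 195, closed_canopy_fraction=0.3, seed=11)


@pytest.fixture(scope="session")
def small_stack():
    return generate_landscape(SyntheticConfig(seed=7), GridSpec(80, 80))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
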