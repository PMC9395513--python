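import numpy as np
import pytest
from hypothesis import settings

from ctmt.stimuli import GridSpec, generate_layout_set

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def grid() -> GridSpec:
    return GridSpec()


@pytest.fixture(scope="session")
def layout_pool(grid):
    """A small pool of accepted layouts shared across tests."""
    layouts, _ = generate_layout_set(grid, 8, seed=20260925)
    return layouts


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
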