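import numpy as np
import pytest

from mitocompare.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact two-clade study reused by read-only tests."""
    return simulate_study(
        SimulationConfig(seed=11, n_teredinid_like=6, n_xylophagaid_like=5)
    )


@pytest.fixture(scope="session")
def full_study():
    """A study at the full geometry (26 + 16 taxa, ~4,135 columns)."""
    return simulate_study(SimulationConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
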