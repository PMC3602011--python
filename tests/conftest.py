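import numpy as np
import pytest

from trillgauge.synthetic_data import PopulationConfig, simulate_population


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete study: 12 males, two seasons."""
    return PopulationConfig(
        n_males=12,
        n_both_years=4,
        trills_per_male=(8, 14),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_population(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
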