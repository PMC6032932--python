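import numpy as np
import pandas as pd
import pytest

from leaftemp import synthetic


@pytest.fixture(scope="session")
def small_scenario():
    """Two-day, one-minute-cadence scenario: cheap but structurally complete."""
    return synthetic.default_scenario(seed=1, n_days=2, cadence_s=60)


@pytest.fixture(scope="session")
def small_microclimate(small_scenario):
    return synthetic.gen_microclimate(small_scenario)


@pytest.fixture(scope="session")
def small_spots(small_scenario):
    return synthetic.gen_stomatal_observations(small_scenario)


@pytest.fixture(scope="session")
def small_leaf_series(small_scenario):
    return synthetic.gen_leaf_temperature_series(small_scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(1)
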