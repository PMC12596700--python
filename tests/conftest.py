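import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from socialstrains.synthdata import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact but fully structured cohort used across the suite."""
    return SimulationConfig(n_groups=4, n_species=20, n_secondary=25, seed=7)


@pytest.fixture(scope="session")
def bundle(small_config):
    return simulate_all(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
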