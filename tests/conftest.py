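import pytest
from hypothesis import HealthCheck, settings

from fgf21val.simulate import SimulationConfig, simulate_cohort, simulate_validation_suite

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def suite(config):
    """One default-design synthetic validation suite, shared across tests."""
    return simulate_validation_suite(config)


@pytest.fixture(scope="session")
def cohort(config):
    df, truth = simulate_cohort(config, seed=11)
    return df, truth
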