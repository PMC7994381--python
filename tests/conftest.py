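import warnings

import pytest
from hypothesis import HealthCheck, settings

from nbscreen import (
    SimulationConfig,
    simulate_chip_fixture,
    simulate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def chip_fixture():
    return simulate_chip_fixture(SimulationConfig(seed=1))


@pytest.fixture(autouse=True)
def _quiet_degenerate_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
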