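import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dectmd.attenuation import EnergyPair
from dectmd.synthetic import (
    CohortConfig,
    cohort_from_frame,
    generate_attenuation_fixture,
    generate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def energies():
    return EnergyPair(e_low=52.0, e_high=75.0)


@pytest.fixture(scope="session")
def table():
    """Fixture attenuation table for the full 27-material library."""
    return generate_attenuation_fixture(seed=0)


@pytest.fixture(scope="session")
def cohort_frame(table, energies):
    return generate_cohort(CohortConfig(seed=7), table, energies)


@pytest.fixture(scope="session")
def cohort(cohort_frame):
    return cohort_from_frame(cohort_frame)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
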