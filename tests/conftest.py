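import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vancoml as v

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return v.PPKParams()


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient cohort with realized clearances (seeded)."""
    cohort = v.generate_cohort(v.CohortSpec(n=60, seed=11))
    etas = v.sample_etas(60, seed=12)
    return v.simulate_individual_cl(cohort, etas)


@pytest.fixture(scope="session")
def labelled_cohort_1000():
    """Default-size cohort with realized clearances, shared across tests."""
    cohort = v.generate_cohort(v.CohortSpec(n=1000, seed=21))
    etas = v.sample_etas(1000, seed=22)
    return v.simulate_individual_cl(cohort, etas)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
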