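import pytest
from hypothesis import settings

from n2bos import CohortConfig, analyze_cohort, generate_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cohort():
    """The default seeded 61-patient synthetic cohort."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    return analyze_cohort(default_cohort.timelines)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Same structure without measurement noise, missingness or dropout."""
    config = CohortConfig(
        seed=1, measurement_cv=0.0, missing_prob={}, dropout_hazard=0.0
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_cohort):
    return analyze_cohort(noiseless_cohort.timelines)
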