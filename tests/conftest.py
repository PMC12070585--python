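import pytest
from hypothesis import HealthCheck, settings

from portfoliodiet import attach_scores, derive_biomarkers, generate_cohort
from portfoliodiet.synthetic import CohortConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort, shared across tests."""
    return generate_cohort(CohortConfig(n_participants=1507, seed=11))


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    """Default cohort with derived biomarkers, scores and tertiles attached."""
    return attach_scores(derive_biomarkers(default_cohort))
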