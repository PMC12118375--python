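import pytest
from hypothesis import HealthCheck, settings

import kneetray as kt

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_cohort():
    """Synthetic cohort at the reference study size."""
    return kt.generate_cohort(kt.GeneratorConfig(n=4980, seed=0))


@pytest.fixture(scope="session")
def big_cohort():
    """Large draw for marginal-convergence checks."""
    return kt.generate_cohort(kt.GeneratorConfig(n=50_000, seed=1))


@pytest.fixture(scope="session")
def recovery_cohort():
    """Very large draw from known coefficients for parameter recovery."""
    return kt.generate_cohort(kt.GeneratorConfig(n=100_000, seed=0))


@pytest.fixture(scope="session")
def recovery_model(recovery_cohort):
    return kt.fit_size_model(recovery_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    return kt.generate_cohort(kt.GeneratorConfig(n=1200, seed=3))


@pytest.fixture(scope="session")
def cv_results(study_cohort):
    """Paired repeated-holdout evaluation of all 12 scenarios (100 reps)."""
    return kt.evaluate_all(study_cohort, kt.CVConfig(replications=100, seed=0),
                           return_replications=True)
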