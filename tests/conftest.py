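import numpy as np
import pytest

from propriolearn.synthetic_cohort import (
    CohortConfig,
    StructuralTraitModel,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 25-participant cohort for fast end-to-end tests."""
    return simulate_cohort(CohortConfig(n_participants=25, seed=11))


@pytest.fixture(scope="session")
def calibrated_cohort():
    """The default calibrated cohort at the size used for cohort-level
    summary checks (built once per session; takes a couple of minutes)."""
    return simulate_cohort(CohortConfig(n_participants=500, seed=7))


@pytest.fixture(scope="session")
def calibrated_metrics(calibrated_cohort):
    from propriolearn.study_pipeline import compute_participant_metrics

    metrics, exclusions = compute_participant_metrics(calibrated_cohort)
    assert exclusions == []
    return metrics


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def default_model():
    return StructuralTraitModel()
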