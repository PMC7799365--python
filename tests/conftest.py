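import numpy as np
import pytest

from alsprs import simulate


@pytest.fixture(scope="session")
def planted_cohort():
    """Default-config cohort with the planted sparse genetic signal."""
    return simulate.simulate_cohort(simulate.CohortConfig(n_subjects=300, seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no genetic signal (all planted weights zero)."""
    cfg = simulate.CohortConfig(n_subjects=300, seed=13, planted_weights=np.zeros(50))
    return simulate.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_estimates(planted_cohort):
    """Mixed-model trajectory estimates for every measure of the planted cohort."""
    from alsprs import trajectories

    return trajectories.fit_all_trajectories(planted_cohort.clinical, planted_cohort.covariates)
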