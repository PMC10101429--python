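import numpy as np
import pytest
from hypothesis import settings

from lexisapc import (APCTruth, LexisGrid, SimConfig, default_truth,
                      simulate_lexis, toy_fixture)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return LexisGrid()


@pytest.fixture(scope="session")
def toy():
    return toy_fixture()


@pytest.fixture(scope="session")
def sim_table(grid):
    """One high-exposure synthetic table with the realistic default truth."""
    return simulate_lexis(SimConfig(grid, default_truth(grid), 1e6, seed=20240901))


@pytest.fixture(scope="session")
def drift_only_truth(grid):
    """Pure drift truth: no curvature, realistic baseline and age curve."""
    base = default_truth(grid)
    return APCTruth(
        baseline_log_rate=base.baseline_log_rate,
        age_curve=base.age_curve,
        drift_per_year=0.008,
        period_curvature=np.zeros(grid.n_periods),
        cohort_curvature=np.zeros(grid.n_cohorts),
    )
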