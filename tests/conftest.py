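import numpy as np
import pytest

from echosic.cross_sectional import standardize_columns
from echosic.simulate import CohortSimConfig, synth_cohort
from echosic.survival import age_quartile_strata


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort (n=2511), with its truth."""
    return synth_cohort(CohortSimConfig(seed=20260901))


@pytest.fixture(scope="session")
def std_cohort(default_cohort):
    """The default cohort with per-SD scaling and age-quartile strata applied."""
    df, _ = default_cohort
    std, params = standardize_columns(
        df, ["hs_sic", "rwt", "bmi", "sbp", "tc_hdl_ratio"]
    )
    return age_quartile_strata(std), params


@pytest.fixture(scope="session")
def large_cohort():
    """A large cohort (n=50,000) for parameter-recovery checks."""
    return synth_cohort(CohortSimConfig(n=50_000, seed=20260902))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
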