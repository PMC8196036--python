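import numpy as np
import pytest

from ctceti.scoring import DEFAULT_POINT_TABLE
from ctceti.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_table():
    return DEFAULT_POINT_TABLE


@pytest.fixture(scope="session")
def small_cohort():
    """120-patient synthetic cohort under default study conditions."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def large_cohort():
    """5000-patient cohort for parameter-recovery checks."""
    return generate_cohort(CohortConfig(n_patients=5000, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
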