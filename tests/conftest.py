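import numpy as np
import pytest

from covadjust.calibration import calibrate
from covadjust.scenarios import TrialScenario


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230606)


@pytest.fixture(scope="session")
def cal_high_incidence():
    """Workhorse scenario: C=0.65, Lambda=0.9, w=1.5, d=0 (cheap searches)."""
    return calibrate(TrialScenario(theta=0.7, w=1.5, d=0.0,
                                   Lambda_target=0.9, C_target=0.65))


@pytest.fixture(scope="session")
def cal_null_covariate():
    """Non-prognostic covariate: C=0.5 so beta = 0."""
    return calibrate(TrialScenario(theta=0.7, w=1.5, d=0.0,
                                   Lambda_target=0.5, C_target=0.5))


@pytest.fixture(scope="session")
def surrogate_table():
    """A default-size synthetic HCC-like cohort (fixed seed)."""
    from covadjust.semisynthetic import generate_surrogate_cohort
    return generate_surrogate_cohort(rng=np.random.default_rng(41))
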