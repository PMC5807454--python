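import numpy as np
import pytest

from hydrocea import CALIBRATION_TARGET_LY, ParameterSet, calibrate_mortality, gompertz_life_table
from hydrocea.demography import LifeTable


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def life_table(params):
    """Life table calibrated so the untreated arm's discounted LY hits the anchor."""
    gp = calibrate_mortality(CALIBRATION_TARGET_LY, params)
    return gompertz_life_table(gp, params.start_age, params.max_age)


@pytest.fixture()
def flat_life_table(params):
    """Constant annual death probability 0.02 across the age range."""
    ages = np.arange(params.start_age, params.max_age + 1)
    q = np.full(ages.shape, 0.02)
    q[-1] = 1.0
    return LifeTable(ages, q)


@pytest.fixture()
def deathless_life_table(params):
    """No background mortality until the forced terminal age."""
    ages = np.arange(params.start_age, params.max_age + 1)
    q = np.zeros(ages.shape)
    q[-1] = 1.0
    return LifeTable(ages, q)
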