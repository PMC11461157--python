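import pytest

from crcscreen.cea import EconParams
from crcscreen.lifetable import DEFAULT_LIFE_TABLE
from crcscreen.nathist import DEFAULT_NATHIST, simulate_cohort


@pytest.fixture(scope="session")
def life_table():
    return DEFAULT_LIFE_TABLE


@pytest.fixture(scope="session")
def econ():
    return EconParams()


@pytest.fixture(scope="session")
def small_cohort(life_table):
    """2,000 persons with the shipped calibration — unit-test scale."""
    return simulate_cohort(DEFAULT_NATHIST, life_table, 2_000, seed=11)


@pytest.fixture(scope="session")
def mid_cohort(life_table):
    """20,000 persons — shared by the heavier acceptance checks."""
    return simulate_cohort(DEFAULT_NATHIST, life_table, 20_000, seed=1)
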