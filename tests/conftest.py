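import numpy as np
import pytest

from lipidcea.markov import LifeTable
from lipidcea.params import default_parameters
from lipidcea.synthetic import default_life_table


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture
def zero_mortality_table():
    ages = np.arange(40, 101, dtype=float)
    return LifeTable(ages, np.zeros_like(ages), np.zeros_like(ages))


@pytest.fixture
def flat_table():
    """Constant 2% all-cause / 0.8% CV mortality at every age."""
    ages = np.arange(40, 101, dtype=float)
    return LifeTable(ages, np.full_like(ages, 0.02), np.full_like(ages, 0.008))
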