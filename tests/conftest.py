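import copy

import numpy as np
import pytest

from colcea import load_basecase, load_life_table
from colcea.mortality import LifeTable


@pytest.fixture(scope="session")
def basecase():
    """Published base-case parameter bundle (session-scoped, treat as const)."""
    return load_basecase()


@pytest.fixture()
def params(basecase):
    """A mutable copy of the base case for tests that perturb inputs."""
    return copy.deepcopy(basecase)


@pytest.fixture(scope="session")
def thai_lt():
    return load_life_table("tha_2019")


@pytest.fixture(scope="session")
def stylized_lt():
    return load_life_table("stylized")


@pytest.fixture(scope="session")
def zero_lt():
    """No background mortality: combined death equals disease death."""
    return LifeTable(np.array([0.0]), np.array([0.0]), max_age=500.0)
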