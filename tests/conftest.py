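import numpy as np
import pytest

from ligannot import fixtures as fx


@pytest.fixture(scope="session")
def dictionary():
    return fx.fixture_dictionary()


@pytest.fixture(scope="session")
def glc(dictionary):
    return dictionary[0]


@pytest.fixture(scope="session")
def ala(dictionary):
    return dictionary[1]


@pytest.fixture(scope="session")
def bnz(dictionary):
    return dictionary[2]


@pytest.fixture(scope="session")
def hoh(dictionary):
    return dictionary[3]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
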