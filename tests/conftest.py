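import numpy as np
import pytest
from hypothesis import settings

from elastomics.pore import PoreModelParams, default_species_catalogue

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return PoreModelParams()


@pytest.fixture(scope="session")
def catalogue():
    return default_species_catalogue()


@pytest.fixture(scope="session")
def species_4k(catalogue):
    return catalogue[0]


@pytest.fixture(scope="session")
def species_500k(catalogue):
    return catalogue[-1]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
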