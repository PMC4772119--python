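import numpy as np
import pytest

from tmdscan import get_scale


@pytest.fixture(scope="session")
def ges():
    return get_scale("GES")


@pytest.fixture(scope="session")
def kd():
    return get_scale("KD")


@pytest.fixture
def rng():
    return np.random.default_rng(20160322)


def random_protein(rng, n, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), size=n))
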