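import numpy as np
import pytest

from eghr import laplace_prior, gaussian_prior


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def laplace():
    return laplace_prior()


@pytest.fixture(scope="session")
def gaussian():
    return gaussian_prior()
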