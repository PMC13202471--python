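import numpy as np
import pytest

from dfon2p import DFONS1, DFONS2, paper_instrument


@pytest.fixture(scope="session")
def instrument():
    """Study instrument with the geometry factor calibrated on dFONs(1)."""
    return paper_instrument()


@pytest.fixture(scope="session")
def dfons1():
    return DFONS1


@pytest.fixture(scope="session")
def dfons2():
    return DFONS2


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
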