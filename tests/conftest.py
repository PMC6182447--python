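import numpy as np
import pytest

from plmdiff import make_simple_sequence


@pytest.fixture(scope="session")
def seq3():
    """The order-3 simple difference sequence used throughout."""
    return make_simple_sequence(3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
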