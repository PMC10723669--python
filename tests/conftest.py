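import numpy as np
import pytest

from aaanet.network import PPINetwork


@pytest.fixture
def path_net():
    """a - b - c."""
    return PPINetwork.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def path_net_isolated():
    """a - b - c plus isolated d."""
    return PPINetwork.from_edges([("a", "b"), ("b", "c")], nodes=["d"])


@pytest.fixture
def triangle():
    return PPINetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def square_diag():
    """a-b-c-d-a plus diagonal a-c."""
    return PPINetwork.from_edges(
        [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")]
    )


@pytest.fixture
def star4():
    """Center 'hub' with 4 leaves."""
    return PPINetwork.from_edges([("hub", f"l{i}") for i in range(4)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
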