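import numpy as np
import pytest

from laplink import network_from_pairs
from laplink.synth import FixtureSpec, planted_block_network, random_bipartite


@pytest.fixture
def diag_net():
    """2x2 network with Y = I: two microbes, two diseases, one edge each."""
    return network_from_pairs([("m1", "d1"), ("m2", "d2")])


@pytest.fixture(scope="session")
def structured_net():
    """Strongly co-clustered fixture: 60 x 20, 3 blocks, p_in=0.6, p_out=0.02."""
    spec = FixtureSpec(nm=60, nd=20, n_blocks=3, p_in=0.6, p_out=0.02, seed=2)
    net, mb, db = planted_block_network(spec)
    return net


@pytest.fixture(scope="session")
def null_net():
    """Unstructured Bernoulli fixture of the same size and similar density."""
    return random_bipartite(FixtureSpec(nm=60, nd=20, density=0.12, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
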