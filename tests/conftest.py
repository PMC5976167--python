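import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from triadnet import Network

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


def random_network(rng, n, p=0.3):
    A = (rng.random((n, n)) < p).astype(np.uint8)
    np.fill_diagonal(A, 0)
    return Network.from_adjacency(A)


@pytest.fixture
def make_random_network(rng):
    def _make(n, p=0.3):
        return random_network(rng, n, p)

    return _make
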