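import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_two_cluster():
    """A tiny, well-separated two-cluster dataset (p=20, n=30)."""
    rng = np.random.default_rng(7)
    p, n = 20, 30
    mu = np.zeros((p, 2))
    mu[:4, 0] = 4.0
    mu[:4, 1] = -4.0
    z = rng.integers(1, 3, size=n)
    Y = mu[:, z - 1] + rng.standard_normal((p, n))
    return Y, z, mu
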