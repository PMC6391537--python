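import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def random_stochastic(rng):
    """Factory for random strictly-positive row-stochastic matrices."""
    def _make(n=20, alpha=1.0):
        return rng.dirichlet(np.full(n, alpha), size=n)
    return _make


@pytest.fixture
def simplex_pair(rng):
    """Factory for pairs of random probability vectors (feature vectors)."""
    def _make(m=20):
        return rng.dirichlet(np.ones(m)), rng.dirichlet(np.ones(m))
    return _make


@pytest.fixture
def random_protein(rng):
    """Factory for aperiodic random sequences over the canonical alphabet."""
    from fimseq.alphabet import AMINO_ACIDS

    def _make(n=200):
        return "".join(rng.choice(AMINO_ACIDS, size=n))
    return _make


def delta(i, m=20):
    v = np.zeros(m)
    v[i] = 1.0
    return v
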