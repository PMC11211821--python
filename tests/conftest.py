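import numpy as np
import pytest

from mvhic.contacts import ContactMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric_counts(rng, n, lam=8.0):
    """Poisson symmetric count matrix helper used across tests."""
    upper = rng.poisson(lam, size=(n, n))
    upper = np.triu(upper)
    return (upper + np.triu(upper, 1).T).astype(float)


@pytest.fixture
def small_map(rng):
    return ContactMap(chrom="chrT", resolution=10_000, counts=random_symmetric_counts(rng, 60))


@pytest.fixture
def decay_map():
    """Deterministic distance-decay (Toeplitz) map: value 100 / (1 + d)."""
    n = 80
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return ContactMap(chrom="chrT", resolution=10_000, counts=100.0 / (1.0 + d))
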