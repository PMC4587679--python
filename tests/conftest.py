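import numpy as np
import pytest

from hicompare.genome import ContactMap, make_binning


@pytest.fixture
def small_binning():
    """Two chromosomes, 10 + 8 bins of 100 kb."""
    return make_binning({"c1": 1_000_000, "c2": 800_000}, 100_000)


@pytest.fixture
def random_map(small_binning):
    """Symmetric random Poisson-count map on the small binning."""
    rng = np.random.default_rng(42)
    n = small_binning.n_bins
    upper = rng.poisson(20.0, size=(n, n))
    values = np.triu(upper) + np.triu(upper, 1).T
    return ContactMap(small_binning, values.astype(float), state="raw")


def symmetric_counts(rng, n, lam=20.0):
    upper = rng.poisson(lam, size=(n, n)).astype(float)
    return np.triu(upper) + np.triu(upper, 1).T
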