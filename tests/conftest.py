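import numpy as np
import pytest

from cdsknn import MixtureSpec, simulate_mixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_blob_embedding():
    """2,000 cells in 5-D, two equal blobs 50 sigma apart."""
    M, labels = simulate_mixture(
        MixtureSpec(n_cells=2000, k=2, dims=5, ir=1.0, separation=50.0, seed=7)
    )
    return M, labels


def random_partition(rng, n, max_parts):
    """A random non-degenerate label vector of length n."""
    while True:
        labels = rng.integers(0, max_parts, size=n)
        if np.unique(labels).size >= 2:
            return labels
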