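import numpy as np
import pytest

from cazlearn import simulate_embeddings


@pytest.fixture(scope="session")
def separable_fixture():
    """Two well-separated Gaussian classes (dim 16, 100/class, 10-sigma)."""
    return simulate_embeddings(2, 100, dim=16, separation=10.0, seed=11)


@pytest.fixture(scope="session")
def ten_family_fixture():
    """Ten planted families, dim 64, 60/class, 6-sigma separation."""
    return simulate_embeddings(10, 60, dim=64, separation=6.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
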