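import numpy as np
import pytest

from triadyn import quantify
from triadyn.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-triad dataset at default (noisy) settings."""
    return simulate_dataset(SimulationConfig(n_triads=300, seed=11))


@pytest.fixture(scope="session")
def small_fpkm(small_dataset):
    return quantify.fpkm(small_dataset.counts, small_dataset.lengths)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def uniform_simplex(n, rng):
    """Uniform points on the 2-simplex (exponential-spacings method)."""
    e = rng.exponential(size=(n, 3))
    return e / e.sum(axis=1, keepdims=True)
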