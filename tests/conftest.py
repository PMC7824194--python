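import numpy as np
import pytest

from capskel import AlphabetMap, StochasticTensor
from capskel import synthetic as syn

BINARY = AlphabetMap(("0", "1"))


def binary_tensor(rows) -> StochasticTensor:
    """Population-style 2x2 tensor from a row list."""
    return StochasticTensor(BINARY, BINARY, np.asarray(rows, dtype=float))


def random_stochastic(rng: np.random.Generator, k_in: int, k_out: int) -> np.ndarray:
    """A strictly positive random row-stochastic matrix."""
    m = rng.gamma(shape=1.0, scale=1.0, size=(k_in, k_out)) + 1e-3
    return m / m.sum(axis=1, keepdims=True)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def chain_net():
    return syn.chain(0.1)


@pytest.fixture(scope="session")
def lucas_net():
    return syn.lucas_like()


@pytest.fixture(scope="session")
def chain_data(chain_net):
    return syn.sample(chain_net, 2000, 42)
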