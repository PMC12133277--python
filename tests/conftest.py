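import numpy as np
import pytest

from trendy.synthetic_data import GroundTruthGRN, SimulationParams, generate_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_spd(rng):
    """Factory for random symmetric positive-definite matrices."""

    def make(n: int) -> np.ndarray:
        b = rng.normal(size=(n, 2 * n))
        return b @ b.T / (2 * n) + 0.1 * np.eye(n)

    return make


@pytest.fixture(scope="session")
def tiny_corpus():
    """Eight small simulated samples shared across tests (n=5 genes)."""
    params = SimulationParams(n_cells=60)
    return generate_corpus(8, n=5, params=params, rng_seed=77)


@pytest.fixture
def zero_grn():
    return GroundTruthGRN(np.zeros((3, 3)))
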