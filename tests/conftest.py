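import numpy as np
import pytest

from pggmob import PayoffLedger, Population, SimulationParams, seed_kernel


@pytest.fixture
def params():
    """Small-lattice defaults used by unit tests."""
    return SimulationParams(L=5, rho=0.5, r=2.0, c=1.0, beta=1.0, gamma=0.7, max_mcs=100, relax_mcs=10, seed=0)


@pytest.fixture
def empty_pop():
    def make(L=5):
        return Population(np.full((L, L), -1, dtype=np.int8))

    return make


@pytest.fixture
def ledger():
    def make(L=5):
        return PayoffLedger(L)

    return make


@pytest.fixture(autouse=True)
def _seeded_kernel():
    """Deterministic kernel RNG for every test."""
    seed_kernel(12345)
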