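import numpy as np
import pytest

from admixtrack import (
    AdmixtureMatrix,
    SimulationConfig,
    TwoWayModelSpec,
    simulate,
)


def random_valid_matrix(rng: np.random.Generator) -> AdmixtureMatrix:
    """A random gene-flow matrix satisfying all invariants.

    K in 2..4, T in 1..60; founding column is a normalized positive vector,
    later columns carry occasional inflow with column sums well below 1.
    """
    K = int(rng.integers(2, 5))
    T = int(rng.integers(1, 61))
    vals = np.zeros((K, T))
    col0 = rng.uniform(0.05, 1.0, size=K)
    vals[:, 0] = col0 / col0.sum()
    for t in range(1, T):
        if rng.random() < 0.3:  # a wave this generation
            total = rng.uniform(0.0, 0.5)
            split = rng.dirichlet(np.ones(K))
            vals[:, t] = total * split
    return AdmixtureMatrix(vals)


@pytest.fixture(scope="session")
def rng_matrices():
    """A fixed batch of random valid matrices for invariant checks."""
    rng = np.random.default_rng(20260919)
    return [random_valid_matrix(rng) for _ in range(200)]


@pytest.fixture(scope="session")
def hi_sim_50():
    """One HI(m=0.3, T=50) forward simulation shared by several tests."""
    chroms, tracks = simulate(
        SimulationConfig(
            matrix=TwoWayModelSpec("HI", 0.3, 50),
            pop_size=1000,
            sample_individuals=200,
            seed=4242,
        )
    )
    return chroms, tracks
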