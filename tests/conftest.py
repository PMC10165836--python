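import logging

import numpy as np
import pytest

from nbsig import CountMatrix, SignatureMatrix, SimulationConfig, simulate_dataset

logging.getLogger("nbsig").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def poisson_dataset():
    """Small Poisson-noise dataset with 3 true signatures, no empty columns."""
    cfg = SimulationConfig(n_patients=25, n_signatures=3, noise="poisson", seed=12)
    data = simulate_dataset(cfg)
    assert (data.counts.values.sum(axis=0) > 0).all()
    return data


@pytest.fixture(scope="session")
def nb10_dataset():
    """Strongly overdispersed dataset (NB noise, alpha=10), 5 signatures."""
    cfg = SimulationConfig(
        n_patients=50, n_signatures=5, noise="negbin_fixed", alpha=10, seed=5
    )
    data = simulate_dataset(cfg)
    assert (data.counts.values.sum(axis=0) > 0).all()
    return data


@pytest.fixture
def exact_rank4():
    """Noise-free counts with an exactly integral rank-4 factorization.

    Signatures are sparse (near-separable) so the factorization is
    identifiable up to permutation; contexts unused by every signature are
    dropped.
    """
    rng = np.random.default_rng(3)
    K, N, M = 4, 40, 96
    probs = rng.dirichlet(np.full(M, 0.08), size=K)
    H = np.array([rng.multinomial(2048, p) for p in probs]) / 2048
    keep = H.sum(axis=0) > 0
    H = H[:, keep]
    W = 2048.0 * rng.integers(1, 15, size=(N, K))
    V = W @ H
    assert np.allclose(V, np.rint(V))
    types = [f"M{m}" for m in range(int(keep.sum()))]
    cm = CountMatrix(np.rint(V), [f"P{n}" for n in range(N)], types)
    truth = SignatureMatrix(H, [f"T{k}" for k in range(K)], types)
    return cm, W, truth
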