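import logging

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

import cofuse

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.disable(logging.WARNING)


@pytest.fixture
def small_truth():
    """Planted ground truth: 60 proteins, 4 complexes, mild overlap."""
    return cofuse.plant_complexes(
        N=60, n_complexes=4, size_min=8, size_max=12, overlap_frac=0.1, seed=11
    )


@pytest.fixture
def block_matrix():
    """Two clean planted blocks of 6 on 12 proteins, as a CoComplexMatrix."""
    index = cofuse.ProteinIndex([f"P{i:02d}" for i in range(12)])
    W = np.zeros((12, 12))
    W[:6, :6] = 1.0
    W[6:, 6:] = 1.0
    np.fill_diagonal(W, 0.0)
    return cofuse.CoComplexMatrix(sp.csr_matrix(W), index)


def random_symmetric(n, density, rng, zero_diag=True):
    """Random symmetric nonnegative sparse matrix (upper triangle sampled)."""
    iu, ju = np.triu_indices(n, k=0 if not zero_diag else 1)
    keep = rng.uniform(size=iu.size) < density
    vals = rng.uniform(0.1, 1.0, size=int(keep.sum()))
    M = sp.coo_matrix((vals, (iu[keep], ju[keep])), shape=(n, n))
    M = M + sp.triu(M, k=1).T
    return M.tocsr()


def random_membership(n, K, rng):
    theta = rng.uniform(size=(n, K))
    return theta / theta.sum(axis=1, keepdims=True)
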