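"""Second-layer integration: similarity network fusion (SNF).

Heterogeneous co-complex matrices (consensus matrices, transformed
affinity scores) live on different scales and carry different noise. SNF
fuses M >= 2 of them by cross diffusion. Two kernels are derived from each
matrix C:

* the full kernel  A_ij = C_ij / (2 sum_{v != i} C_iv) for j != i and
  A_ii = 1/2, which is row-stochastic and independent of the diagonal
  (self-similarity) scale;
* the local kernel B, which keeps for each protein only its L most
  similar neighbours and renormalizes those rows to sum 1.

Starting from W^(m) = A^(m), each status matrix is updated as

    W^(m)  <-  B^(m) . mean_{v != m} W^(v) . B^(m)^T

so that similarity supported by a protein's trusted neighbourhoods in one
view propagates through the remaining views. After each update the status
matrices are renormalized full-kernel style and symmetrized. The fused
result is the average of the converged status matrices.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .core import CoComplexMatrix, logger

__all__ = ["full_kernel", "local_kernel", "fuse"]


def _as_dense(C: CoComplexMatrix | np.ndarray) -> np.ndarray:
    if isinstance(C, CoComplexMatrix):
        return C.toarray()
    return np.asarray(C, dtype=np.float64)


def full_kernel(C: CoComplexMatrix | np.ndarray) -> np.ndarray:
    """Row-stochastic full kernel A; also the per-iteration renormalizer.

    Off-diagonal rows are rescaled to sum 1/2 and the diagonal is pinned
    at 1/2. A protein with an all-zero off-diagonal row gets A_ii = 1 so
    the row stays stochastic (it remains isolated through fusion).
    """
    C = _as_dense(C)
    n = C.shape[0]
    off = C.copy()
    np.fill_diagonal(off, 0.0)
    rowsum = off.sum(axis=1)
    degenerate = rowsum == 0.0
    safe = np.where(degenerate, 1.0, rowsum)
    A = off / (2.0 * safe[:, None])
    diag = np.where(degenerate, 1.0, 0.5)
    A[np.arange(n), np.arange(n)] = diag
    return A


def local_kernel(C: CoComplexMatrix | np.ndarray, L: int) -> np.ndarray:
    """Sparse local kernel B over each protein's L nearest neighbours.

    Neighbourhoods exclude the protein itself and zero-score entries;
    ties at the L-th rank break toward the smaller protein index. Rows
    with no positive neighbour stay all-zero.
    """
    if L < 1:
        raise ValueError("neighbourhood size L must be >= 1")
    C = _as_dense(C)
    n = C.shape[0]
    off = C.copy()
    np.fill_diagonal(off, 0.0)
    B = np.zeros_like(off)
    for i in range(n):
        row = off[i]
        # stable sort on -row: descending score, ties by smaller index
        order = np.argsort(-row, kind="stable")
        top = [j for j in order[:L] if row[j] > 0.0]
        if not top:
            continue
        denom = row[top].sum()
        B[i, top] = row[top] / denom
    return B


def fuse(
    mats: list[CoComplexMatrix],
    L: int = 20,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> CoComplexMatrix:
    """Cross-diffuse M >= 2 co-complex matrices into one fused matrix.

    Stops when the largest entrywise change across status matrices drops
    below ``tol`` or after ``max_iter`` sweeps. The fused matrix is
    symmetrized and its diagonal zeroed (self-similarity carries no
    co-complex information downstream).
    """
    if len(mats) < 2:
        raise ValueError("fusion requires at least two matrices")
    index = mats[0].index
    for m in mats[1:]:
        if m.index != index:
            raise ValueError("all matrices must share one protein index")

    M = len(mats)
    A = [full_kernel(m) for m in mats]
    B = [local_kernel(m, L) for m in mats]
    W = [a.copy() for a in A]

    for t in range(max_iter):
        total = sum(W)
        new: list[np.ndarray] = []
        for m in range(M):
            others = (total - W[m]) / (M - 1)
            Wm = B[m] @ others @ B[m].T
            Wm = full_kernel(Wm)          # full-kernel renormalization restores row-stochasticity
            Wm = 0.5 * (Wm + Wm.T)        # restore exact symmetry
            new.append(Wm)
        delta = max(np.abs(new[m] - W[m]).max() for m in range(M))
        W = new
        if delta < tol:
            logger.info("fuse: converged after %d iterations (delta=%.3g)", t + 1, delta)
            break
    else:
        logger.info("fuse: stopped at max_iter=%d (delta=%.3g)", max_iter, delta)

    fused = sum(W) / M
    fused = 0.5 * (fused + fused.T)
    np.fill_diagonal(fused, 0.0)
    fused[fused < 0] = 0.0  # guard against -0 / roundoff
    return CoComplexMatrix(sp.csr_matrix(fused), index)
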