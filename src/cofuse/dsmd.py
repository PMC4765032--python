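"""Graph-regularized doubly stochastic matrix decomposition.

The fused similarity matrix W is modeled through soft complex memberships
theta (N x K, rows on the simplex), where theta_ik = P(k | i) is the
probability of a single-step random walk from protein i into complex k.
With a uniform prior over proteins, the two-step walk probability between
proteins i and j via all complexes is

    What_ij = sum_k theta_ik theta_jk / sum_z theta_zk,

a doubly stochastic reconstruction (rows and columns each sum to 1). The
fit minimizes the generalized Kullback-Leibler divergence between W and
What plus a graph-Laplacian penalty that pushes strongly connected
proteins toward similar membership rows:

    J(theta) = sum_ij (-W_ij log What_ij + What_ij)
               + lambda (Tr(theta^T D theta) - Tr(theta^T W theta)),

with D_ii = sum_j W_ij. J is non-convex; the solver uses multiplicative
updates obtained by splitting the gradient into positive and negative
parts, exact row renormalization, and a convex-combination backtracking
safeguard, giving a monotone (to numerical slack) objective trace at
O((E + N) K) cost per iteration, E = nnz(W). W is kept sparse throughout.

The continuous solution is discretized per protein by the largest-gap
rule on its sorted membership row, producing overlapping complexes;
complexes with fewer than ``min_size`` (default 3) proteins are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .core import CoComplexMatrix, ComplexSet, Membership, ProteinIndex, logger

__all__ = [
    "FitTrace",
    "reconstruct",
    "objective",
    "laplacian_penalty",
    "fit",
    "discretize",
    "filter_min_size",
]

_EMPTY_COL = 1e-12  # column mass below this is treated as an empty complex


@dataclass
class FitTrace:
    """Objective value per iteration (index 0 = initial point)."""

    objective_per_iter: list[float] = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False


def _check_theta(theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=np.float64)
    if theta.ndim != 2:
        raise ValueError("theta must be 2-D")
    if theta.min() < 0:
        raise ValueError("theta must be nonnegative")
    if np.abs(theta.sum(axis=1) - 1.0).max() > 1e-8:
        raise ValueError("theta rows must lie on the simplex")
    return theta


def reconstruct(theta: Membership | np.ndarray) -> np.ndarray:
    """Dense doubly stochastic reconstruction What from memberships."""
    if isinstance(theta, Membership):
        theta = theta.theta
    theta = _check_theta(theta)
    s = theta.sum(axis=0)
    scale = np.where(s > _EMPTY_COL, s, np.inf)  # empty columns contribute 0
    return (theta / scale) @ theta.T


def _what_at_edges(
    theta: np.ndarray, s: np.ndarray, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """What_ij evaluated only at the (rows, cols) positions — O(E K)."""
    scale = np.where(s > _EMPTY_COL, s, np.inf)
    return np.einsum("ek,ek->e", theta[rows], theta[cols] / scale)


def laplacian_penalty(
    W: CoComplexMatrix | sp.spmatrix | np.ndarray,
    theta: np.ndarray,
    method: str = "trace",
) -> float:
    """Graph-Laplacian smoothness penalty Tr(th^T D th) - Tr(th^T W th).

    ``method="pairwise"`` evaluates the equivalent elementwise form
    (1/2) sum_ij W_ij sum_k (theta_ik - theta_jk)^2; both must agree.
    """
    if isinstance(W, CoComplexMatrix):
        W = W.values
    W = sp.csr_matrix(W, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    if method == "trace":
        d = np.asarray(W.sum(axis=1)).ravel()
        Wth = W @ theta
        return float(np.sum(d[:, None] * theta * theta) - np.sum(theta * Wth))
    if method == "pairwise":
        coo = W.tocoo()
        diff2 = ((theta[coo.row] - theta[coo.col]) ** 2).sum(axis=1)
        return float(0.5 * np.sum(coo.data * diff2))
    raise ValueError(f"unknown method {method!r}")


def objective(
    W: CoComplexMatrix | sp.spmatrix,
    theta: Membership | np.ndarray,
    lambda_: float,
) -> float:
    """Regularized divergence J(theta); +inf if support is violated.

    Uses the 0*log 0 = 0 convention; since theta is row-stochastic the
    total reconstruction mass sum_ij What_ij equals N exactly and is added
    in closed form.
    """
    if isinstance(W, CoComplexMatrix):
        W = W.values
    W = sp.csr_matrix(W, dtype=np.float64)
    if isinstance(theta, Membership):
        theta = theta.theta
    theta = _check_theta(theta)
    n = theta.shape[0]
    coo = sp.triu(W, k=1).tocoo()  # W symmetric, zero diagonal
    s = theta.sum(axis=0)
    what = _what_at_edges(theta, s, coo.row, coo.col)
    if np.any((what <= 0) & (coo.data > 0)):
        return float("inf")
    kl = -2.0 * float(np.sum(coo.data * np.log(what)))  # both ordered pairs
    reg = lambda_ * laplacian_penalty(W, theta) if lambda_ != 0.0 else 0.0
    return kl + float(n) + reg


def fit(
    W: CoComplexMatrix | sp.spmatrix,
    K: int,
    lambda_: float = 32.0,
    max_iter: int = 200,
    tol: float = 1e-9,
    seed: int = 0,
) -> tuple[Membership, FitTrace]:
    """Minimize J(theta) by safeguarded multiplicative updates.

    Stops when the relative objective change over a 10-iteration window
    falls below ``tol`` or at ``max_iter``. Deterministic given ``seed``
    (uniform(0,1) init, row-normalized).
    """
    if isinstance(W, CoComplexMatrix):
        W = W.values
    W = sp.csr_matrix(W, dtype=np.float64)
    if K < 1:
        raise ValueError("K must be >= 1")
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    if W.nnz and W.data.min() < 0:
        raise ValueError("W must be nonnegative")
    n = W.shape[0]
    W = W.copy()
    W.setdiag(0.0)
    W.eliminate_zeros()

    coo = W.tocoo()
    rows, cols, wdata = coo.row, coo.col, coo.data
    d = np.asarray(W.sum(axis=1)).ravel()

    rng = np.random.default_rng(seed)
    theta = rng.uniform(size=(n, K))
    theta /= theta.sum(axis=1, keepdims=True)

    def J(th: np.ndarray) -> float:
        s = th.sum(axis=0)
        what = _what_at_edges(th, s, rows, cols)
        if np.any((what <= 0) & (wdata > 0)):
            return float("inf")
        with np.errstate(divide="ignore"):
            kl = -float(np.sum(wdata * np.log(what)))
        if lambda_ != 0.0:
            reg = lambda_ * (
                float(np.sum(d[:, None] * th * th)) - float(np.sum(th * (W @ th)))
            )
        else:
            reg = 0.0
        return kl + float(n) + reg

    trace = FitTrace(objective_per_iter=[J(theta)])
    window: list[float] = [trace.objective_per_iter[0]]

    for it in range(max_iter):
        J_cur = trace.objective_per_iter[-1]
        s = theta.sum(axis=0)
        scale = np.where(s > _EMPTY_COL, s, np.inf)
        what = _what_at_edges(theta, s, rows, cols)
        Z = sp.csr_matrix(
            (wdata / np.maximum(what, 1e-300), (rows, cols)), shape=W.shape
        )
        Zth = Z @ theta
        q = np.einsum("ik,ik->k", theta, Zth)  # theta_k^T Z theta_k
        Wth = W @ theta
        # gradient split: descent-promoting part gneg, damping part gpos;
        # the row terms a, b carry the simplex multiplier (relaxed MM)
        gneg = 2.0 * Zth / scale + 2.0 * lambda_ * Wth
        gpos = q / scale**2 + 1.0 + 2.0 * lambda_ * d[:, None] * theta
        a = np.sum(theta * gpos, axis=1, keepdims=True)
        b = np.sum(theta * gneg, axis=1, keepdims=True)
        prop = theta * (gneg + a) / (gpos + b)
        rowsum = prop.sum(axis=1)
        dead = rowsum <= 0
        if dead.any():
            prop[dead] = theta[dead]
        prop /= prop.sum(axis=1, keepdims=True)

        # backtracking on the segment theta -> prop keeps feasibility exact
        step = 1.0
        J_new = J(prop)
        cand = prop
        while J_new > J_cur * (1.0 + 1e-12) and step > 1e-6:
            step *= 0.5
            cand = (1.0 - step) * theta + step * prop
            J_new = J(cand)
        if J_new > J_cur * (1.0 + 1e-12):
            trace.converged = True
            trace.iterations_run = it
            logger.info("fit: no descent direction at iteration %d; stopping", it)
            break
        theta = cand
        trace.objective_per_iter.append(J_new)
        trace.iterations_run = it + 1

        window.append(J_new)
        if len(window) > 11:
            window.pop(0)
        if len(window) == 11:
            ref = abs(window[0]) if window[0] != 0 else 1.0
            if (window[0] - window[-1]) / ref < tol:
                trace.converged = True
                break

    theta /= theta.sum(axis=1, keepdims=True)  # exact simplex to 1e-16
    return Membership(theta), trace


def discretize(theta_hat: Membership, index: ProteinIndex) -> ComplexSet:
    """Overlapping hard assignments by the per-protein largest-gap rule.

    Each protein's membership row is sorted descending; the protein joins
    the complexes ranked above the largest consecutive gap (smallest rank
    on ties). With K = 1 every protein joins the single complex. Empty
    columns yield no complex.
    """
    theta = theta_hat.theta
    n, K = theta.shape
    if n != len(index):
        raise ValueError("membership and index sizes differ")
    members: list[list[str]] = [[] for _ in range(K)]
    if K == 1:
        members[0] = list(index.ids)
    else:
        # stable argsort on -row: descending value, ties to smaller column
        order = np.argsort(-theta, axis=1, kind="stable")
        sorted_vals = np.take_along_axis(theta, order, axis=1)
        gaps = sorted_vals[:, :-1] - sorted_vals[:, 1:]
        k_i = np.argmax(gaps, axis=1) + 1  # smallest argmax via first-hit
        for i in range(n):
            for k in order[i, : k_i[i]]:
                members[k].append(index.id(i))
    complexes = [frozenset(m) for m in members if m]
    return ComplexSet(complexes, kind="predicted")


def filter_min_size(cs: ComplexSet, min_size: int = 3) -> ComplexSet:
    """Drop complexes with fewer than ``min_size`` proteins, keeping order."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return ComplexSet(
        [c for c in cs.complexes if len(c) >= min_size], kind=cs.kind
    )
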