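"""Refinement of raw pairwise co-complex affinity scores.

Raw affinity scores computed from TAP purification records (such as C2S
scores) are real-valued and unbounded; negative scores indicate pairs
unlikely to be co-complexed. The refinement discards negatives and maps
positive scores through a saturating exponential:

    C_ij = 1 - exp(-s_ij)   if s_ij > 0,   else 0

which is monotone, bounded in [0, 1), and zero exactly on (-inf, 0].
Computing the raw scores themselves from purification records is upstream
of this package; the transform consumes a precomputed score table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .core import CoComplexMatrix, ProteinIndex, pairs_to_matrix

__all__ = ["RawAffinityTable", "transform_scores"]


@dataclass
class RawAffinityTable:
    """Symmetric sparse table of raw (possibly negative) affinity scores."""

    scores: sp.csr_matrix
    index: ProteinIndex

    def __post_init__(self) -> None:
        self.scores = sp.csr_matrix(self.scores, dtype=np.float64)
        n = len(self.index)
        if self.scores.shape != (n, n):
            raise ValueError("score matrix shape does not match index size")
        S = self.scores.copy()
        S.sort_indices()
        T = self.scores.T.tocsr()
        T.sort_indices()
        # NaN-tolerant symmetry: patterns match and values agree elementwise
        if not (
            np.array_equal(S.indptr, T.indptr)
            and np.array_equal(S.indices, T.indices)
            and np.array_equal(S.data, T.data, equal_nan=True)
        ):
            raise ValueError("raw affinity table must be symmetric")

    @classmethod
    def from_pairs(
        cls, table: dict[tuple[str, str], float], index: ProteinIndex
    ) -> "RawAffinityTable":
        return cls(pairs_to_matrix(table, index, allow_negative=True), index)


def transform_scores(raw: RawAffinityTable) -> CoComplexMatrix:
    """Bounded co-complex matrix from raw affinity scores (see module doc)."""
    coo = raw.scores.tocoo()
    bad = ~np.isfinite(coo.data)
    if bad.any():
        e = int(np.flatnonzero(bad)[0])
        raise ValueError(
            "non-finite affinity score for pair "
            f"({raw.index.id(int(coo.row[e]))}, {raw.index.id(int(coo.col[e]))})"
        )
    keep = coo.data > 0
    vals = 1.0 - np.exp(-coo.data[keep])
    C = sp.coo_matrix(
        (vals, (coo.row[keep], coo.col[keep])), shape=raw.scores.shape
    ).tocsr()
    C.setdiag(0.0)
    C.eliminate_zeros()
    return CoComplexMatrix(C, raw.index)
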