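"""First-layer integration: consensus matrices from base clusterings.

Each data source (e.g., a binary PPI network, TAP purification data)
yields several base clustering results from different detection methods.
The consensus matrix C for a source has entries

    C_ij = (# results in which proteins i and j share a cluster) / n_p

so C_ij estimates the co-complex probability of the pair under the
ensemble. A pair co-clustered in several clusters of the *same* result
still counts once for that result. Proteins assigned to no cluster in any
result, or absent from the source's coverage, get all-zero rows/columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .core import ClusteringResult, CoComplexMatrix, ProteinIndex, logger

__all__ = ["ConsensusSpec", "build_consensus", "matrix_average"]


@dataclass
class ConsensusSpec:
    """Inputs for one source's consensus matrix.

    ``covered`` is the set of proteins present in the source; pairs
    involving uncovered proteins are zeroed even if some base result
    clusters them. Defaults to the union of all cluster members.
    """

    results: list[ClusteringResult]
    index: ProteinIndex
    covered: set[str] | None = None

    def coverage(self) -> set[str]:
        if self.covered is not None:
            return set(self.covered)
        cov: set[str] = set()
        for r in self.results:
            cov.update(r.proteins())
        return cov


def build_consensus(spec: ConsensusSpec) -> CoComplexMatrix:
    """Fraction of base results co-clustering each protein pair."""
    if not spec.results:
        raise ValueError("at least one clustering result is required")
    n = len(spec.index)
    if n == 0:
        raise ValueError("protein index is empty")
    covered = spec.coverage()
    n_p = len(spec.results)

    counts: dict[tuple[int, int], int] = {}
    outside: set[str] = set()
    for result in spec.results:
        seen: set[tuple[int, int]] = set()
        for cluster in result.clusters:
            members = []
            for p in cluster:
                if p not in spec.index:
                    outside.add(p)
                elif p in covered:
                    members.append(spec.index.index(p))
            members.sort()
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    seen.add((members[a], members[b]))
        for pair in seen:
            counts[pair] = counts.get(pair, 0) + 1
    if outside:
        logger.warning(
            "build_consensus: ignored %d cluster members outside the index", len(outside)
        )

    if counts:
        ij = np.array(list(counts.keys()), dtype=np.int64)
        vals = np.array(list(counts.values()), dtype=np.float64) / n_p
        rows = np.concatenate([ij[:, 0], ij[:, 1]])
        cols = np.concatenate([ij[:, 1], ij[:, 0]])
        data = np.concatenate([vals, vals])
        C = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    else:
        C = sp.csr_matrix((n, n))
    return CoComplexMatrix(C, spec.index)


def matrix_average(mats: list[CoComplexMatrix]) -> CoComplexMatrix:
    """Entrywise mean of co-complex matrices — the naive fusion baseline."""
    if len(mats) < 2:
        raise ValueError("matrix averaging needs at least two matrices")
    index = mats[0].index
    for m in mats[1:]:
        if m.index != index:
            raise ValueError("all matrices must share one protein index")
    total = mats[0].values.copy()
    for m in mats[1:]:
        total = total + m.values
    return CoComplexMatrix((total / len(mats)).tocsr(), index)
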