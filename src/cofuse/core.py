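"""Domain types and plain-text I/O for co-complex analysis.

Everything downstream (consensus building, network fusion, matrix
decomposition, evaluation) operates on the small set of containers defined
here: an ordered protein universe (:class:`ProteinIndex`), base clustering
results, symmetric nonnegative co-complex matrices stored sparse, soft
membership matrices on the row simplex, and plain complex sets.

File formats are deliberately simple and text-only:

* cluster lists — one cluster per line, whitespace-separated protein IDs
  (the format MCL and most complex-detection tools emit);
* weighted edge lists — 3-column TSV ``id1  id2  score``;
* matrix triplets — TSV with ``#index`` header lines enumerating the
  protein universe followed by upper-triangle ``i  j  value`` rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger("cofuse")

__all__ = [
    "ProteinIndex",
    "ClusteringResult",
    "CoComplexMatrix",
    "Membership",
    "ComplexSet",
    "Config",
    "read_clusters",
    "write_complexes",
    "read_edge_list",
    "write_edge_list",
    "read_matrix_triplets",
    "write_matrix_triplets",
    "setup_logging",
]


def setup_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    """Route package logs to stderr and optionally to a run log file."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)
    logger.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)


class ProteinIndex:
    """Bijective mapping between protein identifier strings and 0..N-1.

    IDs are case-sensitive opaque strings. The index is immutable once
    built; all matrices sharing an index share one coordinate system.
    """

    __slots__ = ("_ids", "_pos")

    def __init__(self, ids: Iterable[str]):
        self._ids: tuple[str, ...] = tuple(ids)
        self._pos: dict[str, int] = {p: i for i, p in enumerate(self._ids)}
        if len(self._pos) != len(self._ids):
            raise ValueError("protein IDs must be unique")

    @classmethod
    def from_sources(cls, *id_groups: Iterable[str]) -> "ProteinIndex":
        """Build the universe as the sorted union of all input ID groups."""
        universe: set[str] = set()
        for group in id_groups:
            universe.update(group)
        return cls(sorted(universe))

    @property
    def ids(self) -> tuple[str, ...]:
        return self._ids

    def index(self, protein: str) -> int:
        return self._pos[protein]

    def id(self, i: int) -> str:
        return self._ids[i]

    def __len__(self) -> int:
        return len(self._ids)

    def __contains__(self, protein: str) -> bool:
        return protein in self._pos

    def __iter__(self) -> Iterator[str]:
        return iter(self._ids)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ProteinIndex) and self._ids == other._ids

    def __hash__(self) -> int:
        return hash(self._ids)

    def __repr__(self) -> str:
        return f"ProteinIndex(N={len(self)})"


@dataclass
class ClusteringResult:
    """One base method's output: a list of (possibly overlapping) clusters."""

    clusters: list[frozenset[str]]
    source_tag: str = ""

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for c in self.clusters:
            out.update(c)
        return out

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass
class CoComplexMatrix:
    """Symmetric nonnegative N x N co-complex similarity, stored sparse."""

    values: sp.csr_matrix
    index: ProteinIndex

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        n = len(self.index)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match index size {n}"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("co-complex matrix entries must be nonnegative")
        if (self.values != self.values.T).nnz:
            raise ValueError("co-complex matrix must be symmetric as stored")

    @property
    def n(self) -> int:
        return len(self.index)

    def toarray(self) -> np.ndarray:
        return self.values.toarray()

    def reindexed(self, new_index: ProteinIndex) -> "CoComplexMatrix":
        """Permute rows/columns onto ``new_index`` (same ID set required)."""
        if set(new_index.ids) != set(self.index.ids):
            raise ValueError("reindexing requires the same protein universe")
        perm = np.array([self.index.index(p) for p in new_index.ids])
        return CoComplexMatrix(self.values[perm][:, perm].tocsr(), new_index)

    def expanded(self, new_index: ProteinIndex) -> "CoComplexMatrix":
        """Embed into a larger universe; absent proteins get zero rows."""
        missing = [p for p in self.index.ids if p not in new_index]
        if missing:
            raise ValueError(f"target index lacks {len(missing)} proteins, e.g. {missing[0]!r}")
        coo = self.values.tocoo()
        lift = np.array([new_index.index(p) for p in self.index.ids])
        n = len(new_index)
        out = sp.coo_matrix(
            (coo.data, (lift[coo.row], lift[coo.col])), shape=(n, n)
        ).tocsr()
        return CoComplexMatrix(out, new_index)


@dataclass
class Membership:
    """Soft complex assignments: N x K nonnegative, rows on the simplex.

    ``theta[i, k]`` is the probability of assigning protein ``i`` to
    complex ``k``. ``allow_zero_rows`` admits all-zero rows for proteins
    outside every complex (used by planted ground truth); solver output is
    always strict.
    """

    theta: np.ndarray
    allow_zero_rows: bool = False

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=np.float64)
        if self.theta.ndim != 2:
            raise ValueError("theta must be 2-D")
        if self.theta.size and self.theta.min() < 0:
            raise ValueError("theta must be nonnegative")
        rows = self.theta.sum(axis=1)
        ok = np.abs(rows - 1.0) <= 1e-10
        if self.allow_zero_rows:
            ok |= rows == 0.0
        if not ok.all():
            bad = int(np.flatnonzero(~ok)[0])
            raise ValueError(f"theta row {bad} is off the simplex (sum={rows[bad]!r})")

    @property
    def n(self) -> int:
        return self.theta.shape[0]

    @property
    def K(self) -> int:
        return self.theta.shape[1]


@dataclass
class ComplexSet:
    """A list of protein sets — predicted complexes or a benchmark catalog."""

    complexes: list[frozenset[str]]
    kind: str = "predicted"

    def __post_init__(self) -> None:
        if self.kind not in ("predicted", "benchmark"):
            raise ValueError("kind must be 'predicted' or 'benchmark'")
        self.complexes = [frozenset(c) for c in self.complexes]

    def __len__(self) -> int:
        return len(self.complexes)

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for c in self.complexes:
            out.update(c)
        return out

    def as_sets(self) -> set[frozenset[str]]:
        return set(self.complexes)


@dataclass
class Config:
    """Pipeline defaults.

    K and lambda_ follow the published sensitivity analysis (K=2000,
    lambda=2^5); L=20 is the similarity-network-fusion neighbourhood
    default; omega=0.2 is the standard complex-match threshold; complexes
    below min_size=3 are discarded. Iteration/tolerance settings are
    implementation choices.
    """

    K: int = 2000
    lambda_: float = 32.0
    L: int = 20
    snf_max_iter: int = 20
    snf_tol: float = 1e-6
    dsmd_max_iter: int = 200
    dsmd_tol: float = 1e-9
    omega: float = 0.2
    min_size: int = 3
    seed: int = 0


# ---------------------------------------------------------------------------
# cluster-list files
# ---------------------------------------------------------------------------

def read_clusters(path: str | Path, source_tag: str = "") -> ClusteringResult:
    """Read an MCL-style cluster list: one cluster per line.

    Duplicate IDs within a line collapse (set semantics); blank lines are
    skipped; a single-token line yields a size-1 cluster and a warning.
    """
    path = Path(path)
    clusters: list[frozenset[str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            cluster = frozenset(tokens)
            if len(cluster) == 1:
                logger.warning("%s:%d: size-1 cluster %r", path, lineno, tokens[0])
            clusters.append(cluster)
    return ClusteringResult(clusters=clusters, source_tag=source_tag or path.stem)


def write_complexes(cs: ComplexSet, path: str | Path) -> None:
    """Write one complex per line, members sorted for reproducibility."""
    path = Path(path)
    with path.open("w") as fh:
        for c in cs.complexes:
            fh.write(" ".join(sorted(c)) + "\n")


# ---------------------------------------------------------------------------
# weighted edge lists
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> dict[tuple[str, str], float]:
    """Read a 3-column edge list into a symmetric pair->score table.

    Keys are lexicographically sorted ID pairs. A pair seen twice keeps
    the maximum score (logged); self-pairs are dropped.
    """
    path = Path(path)
    table: dict[tuple[str, str], float] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw = parts
            try:
                score = float(raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric score {raw!r}") from exc
            if a == b:
                logger.warning("%s:%d: dropping self-pair %r", path, lineno, a)
                continue
            key = (a, b) if a < b else (b, a)
            if key in table and table[key] != score:
                logger.warning(
                    "%s:%d: duplicate pair %s, keeping max(%g, %g)",
                    path, lineno, key, table[key], score,
                )
                table[key] = max(table[key], score)
            else:
                table[key] = score
    return table


def write_edge_list(table: dict[tuple[str, str], float], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for (a, b), score in sorted(table.items()):
            fh.write(f"{a}\t{b}\t{float(score)!r}\n")


# ---------------------------------------------------------------------------
# matrix triplets
# ---------------------------------------------------------------------------

def write_matrix_triplets(C: CoComplexMatrix, path: str | Path) -> None:
    """Store the upper triangle (i < j) as TSV triplets with an index header."""
    path = Path(path)
    coo = sp.triu(C.values, k=1).tocoo()
    order = np.lexsort((coo.col, coo.row))
    with path.open("w") as fh:
        for i, p in enumerate(C.index.ids):
            fh.write(f"#index\t{i}\t{p}\n")
        for e in order:
            fh.write(f"{coo.row[e]}\t{coo.col[e]}\t{float(coo.data[e])!r}\n")


def read_matrix_triplets(path: str | Path) -> CoComplexMatrix:
    path = Path(path)
    ids: list[str] = []
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if line.startswith("#index"):
                _, i, p = line.rstrip("\n").split("\t")
                if int(i) != len(ids):
                    raise ValueError(f"{path}:{lineno}: index header out of order")
                ids.append(p)
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            if not (0 <= i < j < len(ids)):
                raise ValueError(f"{path}:{lineno}: triplet ({i},{j}) outside upper triangle")
            if not math.isfinite(v):
                raise ValueError(f"{path}:{lineno}: non-finite value")
            rows.append(i)
            cols.append(j)
            vals.append(v)
    index = ProteinIndex(ids)
    n = len(index)
    upper = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    return CoComplexMatrix((upper + upper.T).tocsr(), index)


def pairs_to_matrix(
    table: dict[tuple[str, str], float],
    index: ProteinIndex,
    allow_negative: bool = False,
) -> sp.csr_matrix:
    """Materialize a pair->score table as a symmetric sparse matrix.

    Pairs with members outside the index are skipped with a warning.
    Returned matrix may carry negative scores when ``allow_negative``
    (raw affinity input); it is then NOT a CoComplexMatrix.
    """
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    skipped = 0
    for (a, b), score in table.items():
        if a not in index or b not in index:
            skipped += 1
            continue
        i, j = index.index(a), index.index(b)
        rows += [i, j]
        cols += [j, i]
        vals += [score, score]
    if skipped:
        logger.warning("pairs_to_matrix: skipped %d pairs outside the index", skipped)
    n = len(index)
    M = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    if not allow_negative and M.nnz and M.data.min() < 0:
        raise ValueError("negative scores present; pass allow_negative=True for raw affinities")
    return M
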