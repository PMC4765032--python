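"""Synthetic fixtures: planted complexes, noisy clusterings, affinities.

Real inputs to the pipeline (base clustering result files, a raw TAP
affinity table, a benchmark catalog) require large curated downloads, so
every stage is exercised instead on planted ground truth:

* :func:`plant_complexes` draws overlapping protein complexes with sizes
  uniform in a requested range and a requested fraction of proteins
  belonging to two complexes; remaining proteins are background.
* :func:`perturb_clustering` emulates one base method's imperfect output
  by dropping members, splitting clusters, and merging neighbours.
* :func:`sample_affinity` emulates a raw co-complex affinity score table:
  within-complex pairs score high, a sprinkling of spurious low-scoring
  pairs plays the role of experimental noise.

All randomness flows from explicit seeds; generators never touch global
random state. The distributions are package choices documented in
docs/methods.md, not estimates of any particular screen's error model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .core import (
    ClusteringResult,
    CoComplexMatrix,
    ComplexSet,
    Membership,
    ProteinIndex,
    logger,
    write_complexes,
    write_edge_list,
)

__all__ = [
    "PlantedTruth",
    "plant_complexes",
    "sample_affinity",
    "perturb_clustering",
    "write_fixture_set",
]


@dataclass
class PlantedTruth:
    """Ground-truth complexes plus the index and indicator memberships."""

    truth: ComplexSet
    index: ProteinIndex
    membership: Membership  # indicator rows, row-normalized; zero rows = background
    seed: int

    def within_pair_mask(self) -> np.ndarray:
        """Dense boolean N x N mask of within-complex pairs (zero diagonal)."""
        n = len(self.index)
        mask = np.zeros((n, n), dtype=bool)
        for c in self.truth.complexes:
            idx = np.array([self.index.index(p) for p in c])
            mask[np.ix_(idx, idx)] = True
        np.fill_diagonal(mask, False)
        return mask


def plant_complexes(
    N: int,
    n_complexes: int,
    size_min: int,
    size_max: int,
    overlap_frac: float,
    seed: int,
) -> PlantedTruth:
    """Draw ``n_complexes`` complexes over N proteins with soft overlap.

    Sizes are uniform on [size_min, size_max]. A fraction
    ``overlap_frac`` of the assigned proteins belong to two complexes
    (the rest to one); proteins left over are background. When the drawn
    sizes cannot be packed into N proteins at the requested overlap, the
    overlap count is raised to the minimum that fits (logged); if even
    maximal overlap cannot place the slots, an error explains why.
    """
    if not (1 <= size_min <= size_max):
        raise ValueError("need 1 <= size_min <= size_max")
    if size_max > N:
        raise ValueError(f"size_max={size_max} exceeds N={N}")
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    sizes = rng.integers(size_min, size_max + 1, size=n_complexes)
    total_slots = int(sizes.sum())
    # n_ov proteins fill two slots each: distinct = total_slots - n_ov
    n_ov = int(round(overlap_frac * total_slots / (1.0 + overlap_frac)))
    if total_slots - n_ov > N:
        needed = total_slots - N
        if needed > total_slots // 2:
            raise ValueError(
                f"cannot place {total_slots} membership slots among N={N} "
                f"proteins even with maximal overlap; shrink sizes or raise N"
            )
        logger.warning(
            "plant_complexes: raising overlap count %d -> %d to fit %d slots in N=%d",
            n_ov, needed, total_slots, N,
        )
        n_ov = needed

    ids = [f"P{i:04d}" for i in range(N)]
    index = ProteinIndex(ids)
    pool = rng.permutation(N)
    complexes: list[list[int]] = [[] for _ in range(n_complexes)]
    capacity = sizes.copy()

    cursor = 0
    for _ in range(n_ov):
        # the two complexes with most remaining capacity can always host
        # an overlap protein; random tie-breaking via a small jitter
        open_c = np.flatnonzero(capacity > 0)
        if len(open_c) < 2:
            raise ValueError("overlap request infeasible for the drawn sizes")
        pick = open_c[np.argsort(-(capacity[open_c] + rng.uniform(size=len(open_c))))][:2]
        p = int(pool[cursor]); cursor += 1
        for c in pick:
            complexes[c].append(p)
            capacity[c] -= 1
    for c in range(n_complexes):
        for _ in range(int(capacity[c])):
            complexes[c].append(int(pool[cursor])); cursor += 1

    theta = np.zeros((N, n_complexes))
    for k, members in enumerate(complexes):
        theta[members, k] = 1.0
    rows = theta.sum(axis=1, keepdims=True)
    theta = np.divide(theta, rows, out=np.zeros_like(theta), where=rows > 0)

    truth = ComplexSet(
        [frozenset(ids[p] for p in members) for members in complexes],
        kind="benchmark",
    )
    return PlantedTruth(
        truth=truth,
        index=index,
        membership=Membership(theta, allow_zero_rows=True),
        seed=seed,
    )


def sample_affinity(
    truth: PlantedTruth, p_within: float, noise: float, seed: int
) -> CoComplexMatrix:
    """Raw-score matrix: strong within-complex pairs plus background noise.

    Within-complex pairs score uniform on [p_within - 0.1, p_within]
    (clipped to [0, 1]); every other pair is present with probability
    ``noise`` and scores uniform on (0, noise]. Symmetric, zero diagonal.
    """
    if not 0 <= noise < p_within <= 1:
        raise ValueError("need 0 <= noise < p_within <= 1")
    rng = np.random.default_rng(seed)
    n = len(truth.index)
    within = truth.within_pair_mask()
    iu, ju = np.triu_indices(n, k=1)

    scores = np.zeros((n, n))
    w = within[iu, ju]
    vals = np.clip(rng.uniform(p_within - 0.1, p_within, size=int(w.sum())), 0.0, 1.0)
    scores[iu[w], ju[w]] = vals
    bg = ~w
    present = rng.uniform(size=int(bg.sum())) < noise
    bg_idx = np.flatnonzero(bg)[present]
    if noise > 0 and len(bg_idx):
        scores[iu[bg_idx], ju[bg_idx]] = noise * (
            1.0 - rng.uniform(0.0, 1.0, size=len(bg_idx))
        )  # uniform on (0, noise]
    scores = scores + scores.T
    return CoComplexMatrix(sp.csr_matrix(scores), truth.index)


def perturb_clustering(
    truth: PlantedTruth,
    drop_rate: float,
    split_rate: float,
    merge_rate: float,
    seed: int,
) -> ClusteringResult:
    """One noisy base clustering derived from the planted complexes.

    Each member is dropped with probability ``drop_rate``; each surviving
    cluster is split into two random halves with probability
    ``split_rate``; each consecutive cluster pair is merged with
    probability ``merge_rate``. Empty clusters vanish.
    """
    for name, r in (("drop", drop_rate), ("split", split_rate), ("merge", merge_rate)):
        if not 0 <= r <= 1:
            raise ValueError(f"{name}_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)

    clusters: list[list[str]] = []
    for c in truth.truth.complexes:
        members = [p for p in sorted(c) if rng.uniform() >= drop_rate]
        if members:
            clusters.append(members)

    split: list[list[str]] = []
    for members in clusters:
        if len(members) >= 2 and rng.uniform() < split_rate:
            perm = rng.permutation(len(members))
            half = len(members) // 2
            split.append([members[i] for i in perm[:half]])
            split.append([members[i] for i in perm[half:]])
        else:
            split.append(members)
    split = [m for m in split if m]

    merged: list[list[str]] = []
    i = 0
    while i < len(split):
        if i + 1 < len(split) and rng.uniform() < merge_rate:
            merged.append(split[i] + split[i + 1])
            i += 2
        else:
            merged.append(split[i])
            i += 1

    return ClusteringResult(
        clusters=[frozenset(m) for m in merged if m],
        source_tag=f"perturbed-seed{seed}",
    )


def write_fixture_set(
    out_dir: str | Path,
    N: int = 200,
    n_complexes: int = 10,
    size_min: int = 15,
    size_max: int = 25,
    overlap_frac: float = 0.1,
    n_clusterings: int = 8,
    drop_rate: float = 0.1,
    split_rate: float = 0.1,
    merge_rate: float = 0.05,
    p_within: float = 0.9,
    noise: float = 0.05,
    seed: int = 0,
) -> Path:
    """Write a complete synthetic input set in the standard text formats.

    Produces ``truth.txt`` (benchmark), ``clustering_XX.txt`` base
    results, and ``affinity.tsv`` raw scores under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = plant_complexes(N, n_complexes, size_min, size_max, overlap_frac, seed)
    write_complexes(truth.truth, out / "truth.txt")
    for r in range(n_clusterings):
        cr = perturb_clustering(truth, drop_rate, split_rate, merge_rate, seed * 1000 + r + 1)
        write_complexes(ComplexSet(cr.clusters, kind="predicted"), out / f"clustering_{r:02d}.txt")
    aff = sample_affinity(truth, p_within, noise, seed * 1000 + 999)
    coo = sp.triu(aff.values, k=1).tocoo()
    table = {
        (truth.index.id(int(i)), truth.index.id(int(j))): float(v)
        for i, j, v in zip(coo.row, coo.col, coo.data)
    }
    write_edge_list(table, out / "affinity.tsv")
    return out
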