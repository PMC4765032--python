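"""Scoring predicted complexes against a benchmark catalog.

Four standard complex-level metrics, with T_ij = |x_i ∩ y_j| the overlap
between benchmark complex x_i and predicted complex y_j:

* Sn  = sum_i max_j T_ij / sum_i |x_i| — how completely benchmark
  complexes are covered by their best-matching predictions;
* PPV = sum_j max_i T_ij / sum_j |y_j ∩ (∪_i x_i)| — how specifically
  predictions map onto single benchmark complexes (the denominator counts
  only predicted members that appear in some benchmark complex);
* Accuracy = sqrt(Sn * PPV), their geometric mean;
* FRAC — the fraction of benchmark complexes matched by at least one
  prediction under the overlap score |x ∩ y|^2 / (|x| |y|) >= omega,
  with omega = 0.2 by convention.

Matching is many-to-many: no one-to-one assignment is enforced. Before
scoring, benchmark complexes are restricted to the proteins present in the
input data and those falling below 3 members are dropped, which avoids
penalizing predictions for proteins the input could never have assigned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .core import ComplexSet, ProteinIndex

__all__ = [
    "EvalReport",
    "overlap_score",
    "sn_ppv_accuracy",
    "frac",
    "filter_benchmark",
    "evaluate",
]


@dataclass
class EvalReport:
    Sn: float
    PPV: float
    Accuracy: float
    FRAC: float
    n_predicted: int
    n_benchmark: int
    matches: list[tuple[int, int, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "Sn": self.Sn,
            "PPV": self.PPV,
            "Accuracy": self.Accuracy,
            "FRAC": self.FRAC,
            "n_predicted": self.n_predicted,
            "n_benchmark": self.n_benchmark,
            "n_matched_benchmark": len({m[0] for m in self.matches}),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def overlap_score(x: frozenset[str] | set[str], y: frozenset[str] | set[str]) -> float:
    """Neighbourhood affinity |x ∩ y|^2 / (|x| |y|) in [0, 1]."""
    if not x or not y:
        raise ValueError("overlap_score requires non-empty sets")
    inter = len(set(x) & set(y))
    return inter * inter / (len(x) * len(y))


def sn_ppv_accuracy(
    benchmark: ComplexSet, predicted: ComplexSet
) -> tuple[float, float, float]:
    """Sensitivity, positive predictive value, and their geometric mean."""
    if len(benchmark) == 0:
        raise ValueError("benchmark must be non-empty")
    if any(not x for x in benchmark.complexes):
        raise ValueError("benchmark complexes must be non-empty")
    if len(predicted) == 0:
        return 0.0, 0.0, 0.0

    bench_union = benchmark.proteins()
    sn_num = 0
    sn_den = 0
    for x in benchmark.complexes:
        sn_den += len(x)
        sn_num += max((len(x & y) for y in predicted.complexes), default=0)
    ppv_num = 0
    ppv_den = 0
    for y in predicted.complexes:
        ppv_num += max((len(x & y) for x in benchmark.complexes), default=0)
        ppv_den += len(y & bench_union)

    sn = sn_num / sn_den
    ppv = ppv_num / ppv_den if ppv_den > 0 else 0.0
    return sn, ppv, (sn * ppv) ** 0.5


def frac(
    benchmark: ComplexSet, predicted: ComplexSet, omega: float = 0.2
) -> tuple[float, list[tuple[int, int, float]]]:
    """Fraction of benchmark complexes matched at overlap score >= omega.

    Returns (FRAC, matches) where matches lists every qualifying
    (benchmark index, predicted index, overlap score) pair.
    """
    if not 0 < omega <= 1:
        raise ValueError("omega must be in (0, 1]")
    if len(benchmark) == 0:
        raise ValueError("benchmark must be non-empty")
    matches: list[tuple[int, int, float]] = []
    matched: set[int] = set()
    for i, x in enumerate(benchmark.complexes):
        for j, y in enumerate(predicted.complexes):
            score = overlap_score(x, y)
            if score >= omega:
                matches.append((i, j, score))
                matched.add(i)
    return len(matched) / len(benchmark), matches


def filter_benchmark(
    benchmark: ComplexSet, universe: ProteinIndex | set[str], min_size: int = 3
) -> ComplexSet:
    """Restrict benchmark complexes to the data's protein universe.

    Members outside the universe are removed; complexes shrinking below
    ``min_size`` are dropped.
    """
    members = set(universe.ids) if isinstance(universe, ProteinIndex) else set(universe)
    kept = []
    for c in benchmark.complexes:
        reduced = c & members
        if len(reduced) >= min_size:
            kept.append(frozenset(reduced))
    return ComplexSet(kept, kind="benchmark")


def evaluate(
    benchmark: ComplexSet, predicted: ComplexSet, omega: float = 0.2
) -> EvalReport:
    """Full metric report for one predicted set against one benchmark."""
    sn, ppv, acc = sn_ppv_accuracy(benchmark, predicted)
    f, matches = frac(benchmark, predicted, omega)
    return EvalReport(
        Sn=sn,
        PPV=ppv,
        Accuracy=acc,
        FRAC=f,
        n_predicted=len(predicted),
        n_benchmark=len(benchmark),
        matches=matches,
    )
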