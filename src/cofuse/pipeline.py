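"""End-to-end pipeline: consensus -> transform -> fuse -> detect -> evaluate.

The pipeline is a pure function of its inputs, configuration, and seed:
rerunning with the same config reproduces the complexes file byte for
byte. Configuration is a flat TOML file; unknown keys are rejected and a
resolved copy is written next to the outputs.
"""

from __future__ import annotations

import json
import time
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import dsmd
from .affinity import RawAffinityTable, transform_scores
from .consensus import ConsensusSpec, build_consensus, matrix_average
from .core import (
    CoComplexMatrix,
    ComplexSet,
    Config,
    ProteinIndex,
    logger,
    read_clusters,
    read_edge_list,
    write_complexes,
    write_matrix_triplets,
)
from .evaluation import evaluate, filter_benchmark
from .fusion import fuse

__all__ = ["PipelineConfig", "run_pipeline", "sweep"]

_KNOWN_KEYS = {
    "cluster_sources",
    "affinity",
    "benchmark",
    "out_dir",
    "fusion_method",
    "K",
    "lambda",
    "L",
    "snf_max_iter",
    "snf_tol",
    "dsmd_max_iter",
    "dsmd_tol",
    "omega",
    "min_size",
    "seed",
}


@dataclass
class PipelineConfig:
    """Inputs and per-stage parameters for one pipeline run.

    ``cluster_sources`` maps a source tag (e.g. "ppi", "tap") to the list
    of base clustering files for that source; each source yields one
    consensus matrix. ``affinity`` optionally names a raw score edge list
    (transformed into an extra matrix). ``fusion_method`` is "snf" or
    "average".
    """

    cluster_sources: dict[str, list[str]]
    out_dir: str
    affinity: str | None = None
    benchmark: str | None = None
    fusion_method: str = "snf"
    params: Config = field(default_factory=Config)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cluster_sources" not in raw or "out_dir" not in raw:
            raise ValueError("config requires 'cluster_sources' and 'out_dir'")
        params = Config(
            K=raw.get("K", Config.K),
            lambda_=raw.get("lambda", Config.lambda_),
            L=raw.get("L", Config.L),
            snf_max_iter=raw.get("snf_max_iter", Config.snf_max_iter),
            snf_tol=raw.get("snf_tol", Config.snf_tol),
            dsmd_max_iter=raw.get("dsmd_max_iter", Config.dsmd_max_iter),
            dsmd_tol=raw.get("dsmd_tol", Config.dsmd_tol),
            omega=raw.get("omega", Config.omega),
            min_size=raw.get("min_size", Config.min_size),
            seed=raw.get("seed", Config.seed),
        )
        return cls(
            cluster_sources={k: list(v) for k, v in raw["cluster_sources"].items()},
            out_dir=raw["out_dir"],
            affinity=raw.get("affinity"),
            benchmark=raw.get("benchmark"),
            fusion_method=raw.get("fusion_method", "snf"),
            params=params,
        )

    def resolved(self) -> dict:
        out = {
            "cluster_sources": self.cluster_sources,
            "out_dir": self.out_dir,
            "affinity": self.affinity,
            "benchmark": self.benchmark,
            "fusion_method": self.fusion_method,
        }
        out.update(asdict(self.params))
        return out


def _build_matrices(cfg: PipelineConfig) -> tuple[ProteinIndex, list[CoComplexMatrix], dict]:
    """Read inputs, build the shared index, and form all co-complex matrices."""
    sources = {
        tag: [read_clusters(f, source_tag=tag) for f in files]
        for tag, files in cfg.cluster_sources.items()
    }
    affinity_table = read_edge_list(cfg.affinity) if cfg.affinity else None

    groups = [r.proteins() for results in sources.values() for r in results]
    if affinity_table:
        groups.append({p for pair in affinity_table for p in pair})
    index = ProteinIndex.from_sources(*groups)

    mats: list[CoComplexMatrix] = []
    names: list[str] = []
    for tag, results in sources.items():
        mats.append(build_consensus(ConsensusSpec(results=results, index=index)))
        names.append(f"consensus_{tag}")
    if affinity_table is not None:
        raw = RawAffinityTable.from_pairs(affinity_table, index)
        mats.append(transform_scores(raw))
        names.append("affinity_transformed")
    return index, mats, {"matrix_names": names}


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory.

    Writes each intermediate matrix, the predicted complexes, the
    resolved configuration, and (when a benchmark is given) the metric
    report.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = cfg.params
    timings: dict[str, float] = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs", name, timings[name])
        return result

    index, mats, meta = stage("build_matrices", lambda: _build_matrices(cfg))
    for name, m in zip(meta["matrix_names"], mats):
        write_matrix_triplets(m, out / f"{name}.tsv")

    if cfg.fusion_method == "snf":
        W = stage("fuse", lambda: fuse(mats, L=p.L, max_iter=p.snf_max_iter, tol=p.snf_tol))
    elif cfg.fusion_method == "average":
        W = stage("fuse", lambda: matrix_average(mats))
    else:
        raise ValueError(f"unknown fusion_method {cfg.fusion_method!r}")
    write_matrix_triplets(W, out / "fused.tsv")

    theta, trace = stage(
        "decompose",
        lambda: dsmd.fit(W, K=p.K, lambda_=p.lambda_, max_iter=p.dsmd_max_iter,
                         tol=p.dsmd_tol, seed=p.seed),
    )
    complexes = dsmd.filter_min_size(dsmd.discretize(theta, index), p.min_size)
    write_complexes(complexes, out / "complexes.txt")
    with (out / "trace.tsv").open("w") as fh:
        for i, v in enumerate(trace.objective_per_iter):
            fh.write(f"{i}\t{float(v)!r}\n")

    if cfg.benchmark:
        bench = ComplexSet(read_clusters(cfg.benchmark).clusters, kind="benchmark")
        bench = filter_benchmark(bench, index, min_size=p.min_size)
        report = stage("evaluate", lambda: evaluate(bench, complexes, omega=p.omega))
        report.save(out / "report.json")
    else:
        logger.info("no benchmark given; evaluation skipped")

    resolved = cfg.resolved()
    resolved["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    (out / "resolved_config.json").write_text(json.dumps(resolved, indent=2) + "\n")
    return out


def sweep(
    cfg: PipelineConfig, K_grid: list[int], lambda_grid: list[float]
) -> list[dict]:
    """Sensitivity sweep over (K, lambda), sharing the upstream matrices.

    Requires a benchmark. Returns one row per grid point, sorted by
    (K, lambda), with Accuracy and FRAC.
    """
    if not K_grid or not lambda_grid:
        raise ValueError("grids must be non-empty")
    if not cfg.benchmark:
        raise ValueError("sweep requires a benchmark")
    K_grid = sorted(set(K_grid))
    lambda_grid = sorted(set(lambda_grid))
    p = cfg.params

    index, mats, _ = _build_matrices(cfg)
    if cfg.fusion_method == "snf":
        W = fuse(mats, L=p.L, max_iter=p.snf_max_iter, tol=p.snf_tol)
    else:
        W = matrix_average(mats)
    bench = ComplexSet(read_clusters(cfg.benchmark).clusters, kind="benchmark")
    bench = filter_benchmark(bench, index, min_size=p.min_size)

    rows: list[dict] = []
    for K in K_grid:
        for lam in lambda_grid:
            theta, _ = dsmd.fit(W, K=K, lambda_=lam, max_iter=p.dsmd_max_iter,
                                tol=p.dsmd_tol, seed=p.seed)
            complexes = dsmd.filter_min_size(dsmd.discretize(theta, index), p.min_size)
            rep = evaluate(bench, complexes, omega=p.omega)
            rows.append({
                "K": K,
                "lambda": lam,
                "Accuracy": rep.Accuracy,
                "FRAC": rep.FRAC,
                "n_predicted": rep.n_predicted,
            })
    return rows
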