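"""Orchestration of the iterative module-discovery loop.

Each iteration (a) sparsifies the remaining genes at the current sparsity
level, (b) runs K-means on those sparse vectors, (c) cross-validates a sparse
representation of every cluster centroid and scores it, (d) retains the union
of the top-P% clusters by CV R^2 and the clusters passing the R^2 threshold
and size window.  Retained clusters become final modules; the rest of the
genes carry into the next iteration at sparsity + 2, until the sparsity
budget, the gene pool, or the iteration cap is exhausted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import metrics as _metrics
from .centroid import Module, score_module, select_sparsity_cv
from .cluster import cluster_sparse
from .io import ExpressionMatrix, make_splits, normalize_genes, variance_filter
from .sparse import sparsify_all

logger = logging.getLogger(__name__)

__all__ = [
    "CamodiConfig",
    "IterationStats",
    "run_camodi",
    "run_bootstraps",
    "tune_parameters",
]


@dataclass(frozen=True)
class CamodiConfig:
    """All tuning parameters of the discovery loop.

    c1/c2 bound the regulators per gene representation and per centroid;
    s1_init/s1_step control the sparsity schedule; k is the K-means cluster
    count (scaled with the shrinking gene pool when ``k_scaling='scaled'``);
    p_keep (percent), r_thresh and the [n_min, n_max] size window govern
    cluster retention; l2_gene/l2_centroid are the two fixed L2 penalties.
    """

    c1: int = 10
    c2: int = 10
    s1_init: int = 1
    s1_step: int = 2
    k: int = 100
    p_keep: float = 10.0
    r_thresh: float = 0.6
    n_min: int = 5
    n_max: int = 1000
    l2_gene: float = 1e-3
    l2_centroid: float = 1e-3
    n_folds: int = 10
    max_iterations: int = 10
    base_seed: int = 0
    k_scaling: str = "scaled"
    variance_fraction: float = 1.0
    normalize_train_only: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.s1_init <= self.c1:
            raise ValueError("require 1 <= s1_init <= c1")
        if not 0 < self.p_keep <= 100:
            raise ValueError("p_keep must be in (0, 100]")
        if self.n_min < 2:
            raise ValueError("n_min must be >= 2")
        if self.n_max <= self.n_min:
            raise ValueError("n_max must exceed n_min")
        if self.k_scaling not in ("fixed", "scaled"):
            raise ValueError("k_scaling must be 'fixed' or 'scaled'")
        if not 0 < self.variance_fraction <= 1:
            raise ValueError("variance_fraction must be in (0, 1]")

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "CamodiConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} is not a flat key/value mapping")
        return cls(**data)


@dataclass(frozen=True)
class IterationStats:
    """One line of the per-iteration log, exposed for instrumentation."""

    iteration: int
    sparsity: int
    clusters_formed: int
    clusters_retained: int
    genes_remaining: int


def _iteration_k(config: CamodiConfig, n_remaining: int, n_initial: int) -> int:
    if config.k_scaling == "fixed":
        k = config.k
    else:
        k = max(2, round(config.k * n_remaining / n_initial))
    return min(k, n_remaining)


def run_camodi(
    x_train: ExpressionMatrix,
    config: CamodiConfig,
    history: list[IterationStats] | None = None,
) -> tuple[list[Module], set[str]]:
    """Run the iterative discovery loop on training-sample expression.

    Returns the discovered modules (disjoint gene sets) and the IDs of genes
    left unassigned.  ``history``, if given, collects per-iteration stats.
    """
    reg_ids = x_train.regulator_ids
    if not reg_ids:
        raise ValueError("no regulator-flagged genes in the matrix")
    reg_matrix = np.stack([x_train.row(r) for r in reg_ids])
    remaining = list(x_train.gene_ids)
    n_initial = len(remaining)
    modules: list[Module] = []

    for t in range(1, config.max_iterations + 1):
        if len(remaining) < config.n_min:
            break
        s_raw = config.s1_init + (t - 1) * config.s1_step
        s = min(s_raw, config.c1)
        reps = sparsify_all(x_train, remaining, c1=s, l2_penalty=config.l2_gene)
        k_t = _iteration_k(config, len(remaining), n_initial)
        assign = cluster_sparse(
            {g: reps[g].reps[s] for g in remaining},
            k=k_t,
            seed=config.base_seed + 7919 * t,
        )
        n_formed = assign.n_clusters
        scored: list[tuple[int, list[str], float, np.ndarray]] = []
        for c in range(1, n_formed + 1):
            members = assign.members(c)
            if len(members) < 2:
                scored.append((c, members, -np.inf, np.zeros(len(reg_ids))))
                continue
            rows = np.stack([x_train.row(g) for g in members])
            _, coef, cv = select_sparsity_cv(
                rows,
                reg_matrix,
                c2=config.c2,
                l2_penalty=config.l2_centroid,
                n_folds=config.n_folds,
                seed=config.base_seed + 104729 * t + c,
            )
            scored.append((c, members, cv, coef))

        n_top = math.ceil(config.p_keep / 100.0 * n_formed)
        by_cv = sorted(scored, key=lambda rec: (-rec[2], rec[0]))
        retained_ids = {rec[0] for rec in by_cv[:n_top]}
        retained_ids |= {
            c
            for c, members, cv, _ in scored
            if cv > config.r_thresh and config.n_min <= len(members) <= config.n_max
        }

        next_remaining: list[str] = []
        n_retained = 0
        for c, members, cv, coef in scored:
            if c in retained_ids and members:
                n_retained += 1
                support = np.flatnonzero(coef)
                coeffs = {reg_ids[i]: float(coef[i]) for i in support}
                modules.append(
                    Module(
                        module_id=f"m{len(modules) + 1:03d}",
                        genes=tuple(members),
                        regulators=tuple(reg_ids[i] for i in support),
                        coefficients=coeffs,
                        cv_r2=None if cv == -np.inf else cv,
                    )
                )
            else:
                next_remaining.extend(members)

        logger.info(
            "iteration %d: sparsity=%d clusters=%d retained=%d remaining=%d",
            t,
            s,
            n_formed,
            n_retained,
            len(next_remaining),
        )
        if history is not None:
            history.append(
                IterationStats(t, s, n_formed, n_retained, len(next_remaining))
            )
        remaining = next_remaining
        if s_raw >= config.c1:  # sparsity budget exhausted
            break
        if n_formed == 0:
            logger.warning("no clusters formed; terminating")
            break

    return modules, set(remaining)


def run_bootstraps(
    x: ExpressionMatrix, config: CamodiConfig, n_bootstraps: int
) -> list[_metrics.BootstrapResult]:
    """Full protocol over random 70/30 splits.

    Per bootstrap: z-normalize genes (on all samples by default, train-only if
    configured), variance-filter on the training samples, run the discovery
    loop on the training columns, then score every module on train and test
    samples.  Deterministic given ``config.base_seed``.
    """
    if n_bootstraps < 1:
        raise ValueError("n_bootstraps must be >= 1")
    splits = make_splits(x, n_bootstraps, config.base_seed)
    results = []
    for split in splits:
        xn = normalize_genes(
            x, sample_ids=split.train_sample_ids if config.normalize_train_only else None
        )
        kept = variance_filter(xn, config.variance_fraction, split)
        xf = xn.subset(genes=kept)
        x_tr = xf.subset(samples=list(split.train_sample_ids))
        cfg = replace(config, base_seed=config.base_seed + 100003 * split.index)
        modules, _ = run_camodi(x_tr, cfg)
        scored = []
        for mod in modules:
            r2_tr, _ = score_module(mod, xf, split.train_sample_ids)
            r2_te, adj_te = score_module(mod, xf, split.test_sample_ids)
            scored.append(mod.scored(r2_train=r2_tr, r2_test=r2_te, adj_r2_test=adj_te))
        summary = _metrics.summarize(_metrics.reporting_filter(scored))
        results.append(
            _metrics.BootstrapResult(split=split, modules=tuple(scored), summary=summary)
        )
    return results


def _objective(results: Sequence[_metrics.BootstrapResult]) -> float:
    adj = [
        m.adj_r2_test
        for res in results
        for m in res.modules
        if m.adj_r2_test is not None
    ]
    return float(np.mean(adj)) if adj else -np.inf


def tune_parameters(
    x: ExpressionMatrix,
    start: CamodiConfig,
    grid: Mapping[str, Sequence],
    n_bootstraps: int = 2,
    tolerance: float = 0.005,
) -> CamodiConfig:
    """Greedy coordinate ascent on the mean adjusted R^2 over bootstraps.

    From ``start``, repeatedly evaluate every single-parameter change drawn
    from ``grid`` and adopt the one with the largest improvement, stopping
    once no change improves the objective by more than ``tolerance``.
    """
    grid = {k: list(v) for k, v in grid.items() if v}
    if not grid:
        logger.warning("empty tuning grid; returning start configuration")
        return start
    current = start
    best = _objective(run_bootstraps(x, current, n_bootstraps))
    logger.info("tuning start: objective=%.4f", best)
    while True:
        best_change: tuple[str, object, float] | None = None
        for param, values in grid.items():
            for value in values:
                if getattr(current, param) == value:
                    continue
                candidate = replace(current, **{param: value})
                score = _objective(run_bootstraps(x, candidate, n_bootstraps))
                logger.info("tune %s=%r -> objective=%.4f", param, value, score)
                if best_change is None or score > best_change[2]:
                    best_change = (param, value, score)
        if best_change is None or best_change[2] <= best + tolerance:
            break
        param, value, best = best_change
        current = replace(current, **{param: value})
        logger.info("adopted %s=%r (objective=%.4f)", param, value, best)
    return current
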