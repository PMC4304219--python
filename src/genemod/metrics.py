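"""Evaluation criteria: R^2 aggregation, bootstrap consistency, homogeneity.

Consistency S measures stability across random 70/30 train/test splits: for
every pair of bootstraps, each module is matched to its most similar module
in the other bootstrap by the average Jaccard index over gene and regulator
sets, and all matched similarities are averaged.  Homogeneity H is the mean
within-module pairwise Pearson correlation, averaged over modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .centroid import Module

if TYPE_CHECKING:  # pragma: no cover
    from .io import BootstrapSplit, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapResult",
    "ResultSummary",
    "jaccard",
    "avg_module_jaccard",
    "consistency",
    "homogeneity",
    "reporting_filter",
    "summarize",
]


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|a & b| / |a | b|; two empty sets count as identical (1.0)."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def avg_module_jaccard(m1: Module, m2: Module) -> float:
    """Mean of the gene-set and regulator-set Jaccard indices."""
    return 0.5 * (jaccard(m1.genes, m2.genes) + jaccard(m1.regulators, m2.regulators))


@dataclass(frozen=True)
class ResultSummary:
    mean_adj_r2_test: float
    mean_n_regulators: float
    n_modules: int


@dataclass(frozen=True)
class BootstrapResult:
    """Modules discovered on one train/test split, with reporting summary."""

    split: "BootstrapSplit"
    modules: tuple[Module, ...]
    summary: ResultSummary

    def __post_init__(self) -> None:
        object.__setattr__(self, "modules", tuple(self.modules))


def summarize(modules: Sequence[Module]) -> ResultSummary:
    """Summary statistics over a (typically reporting-filtered) module set."""
    if not modules:
        return ResultSummary(float("nan"), float("nan"), 0)
    adj = [m.adj_r2_test for m in modules if m.adj_r2_test is not None]
    return ResultSummary(
        mean_adj_r2_test=float(np.mean(adj)) if adj else float("nan"),
        mean_n_regulators=float(np.mean([len(m.regulators) for m in modules])),
        n_modules=len(modules),
    )


def _modules_of(result) -> Sequence[Module]:
    return result.modules if hasattr(result, "modules") else result


def consistency(results: Sequence) -> float:
    """Stability S of the module sets across bootstraps.

    ``results`` holds >= 2 bootstraps, each a :class:`BootstrapResult` or a
    plain module list.  For each unordered pair of bootstraps, every module on
    either side is matched to its best average-Jaccard counterpart on the
    other side (ties to the first by index); the pair score is the mean of the
    N_a + N_b matched similarities, and S averages the pair scores.
    """
    module_sets = [list(_modules_of(r)) for r in results]
    if len(module_sets) < 2:
        raise ValueError("consistency needs >= 2 bootstraps")
    for idx, ms in enumerate(module_sets, start=1):
        if not ms:
            raise ValueError(f"bootstrap {idx} has no modules")
    pair_scores = []
    for a, b in combinations(range(len(module_sets)), 2):
        matched = []
        for src, dst in ((a, b), (b, a)):
            for mod in module_sets[src]:
                matched.append(
                    max(avg_module_jaccard(mod, other) for other in module_sets[dst])
                )
        pair_scores.append(float(np.mean(matched)))
    return float(np.mean(pair_scores))


def homogeneity(
    modules: Sequence[Module],
    x: "ExpressionMatrix",
    sample_ids: Sequence[str] | None = None,
) -> float:
    """Mean within-module pairwise Pearson correlation, averaged over modules.

    Per module, each gene's mean correlation with every other member gene is
    computed and averaged over genes; H averages the module values.  Modules
    with fewer than 2 genes are excluded with a warning.
    """
    sub = x if sample_ids is None else x.subset(samples=list(sample_ids))
    per_module = []
    for mod in modules:
        if len(mod.genes) < 2:
            logger.warning("module %s has < 2 genes; excluded from H", mod.module_id)
            continue
        rows = np.stack([sub.row(g) for g in mod.genes])
        corr = np.corrcoef(rows)
        n = corr.shape[0]
        gene_means = (corr.sum(axis=1) - 1.0) / (n - 1)
        per_module.append(float(gene_means.mean()))
    if not per_module:
        raise ValueError("no module with >= 2 genes")
    return float(np.mean(per_module))


def reporting_filter(
    modules: Sequence[Module],
    min_genes: int = 5,
    max_genes: int = 1000,
    coverage: float = 0.8,
    denominator: str = "filtered",
) -> list[Module]:
    """Evaluation-protocol filter: size window, then coverage prefix.

    Drops modules outside [min_genes, max_genes], sorts the rest by
    ``adj_r2_test`` descending, and keeps the shortest prefix whose union of
    member genes covers at least ``coverage`` of the gene universe.  The
    universe is the genes of the size-filtered modules (``denominator=
    "filtered"``) or of all input modules (``denominator="all"``).
    """
    sized = [m for m in modules if min_genes <= len(m.genes) <= max_genes]
    if not sized:
        return []
    if denominator == "filtered":
        universe = set().union(*(set(m.genes) for m in sized))
    elif denominator == "all":
        universe = set().union(*(set(m.genes) for m in modules))
    else:
        raise ValueError("denominator must be 'filtered' or 'all'")
    ranked = sorted(
        sized,
        key=lambda m: (-(m.adj_r2_test if m.adj_r2_test is not None else -np.inf)),
    )
    covered: set[str] = set()
    prefix: list[Module] = []
    target = coverage * len(universe)
    for mod in ranked:
        prefix.append(mod)
        covered |= set(mod.genes)
        if len(covered) >= target:
            break
    return prefix
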