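"""Module type, shared-prediction scoring, and centroid sparsification.

A module is a gene set G plus a regulator set R with one coefficient per
regulator; every gene in G shares the single prediction
``pred(k) = sum_j alpha_j * s_j(k)``.  The module R^2 compares that shared
prediction against all member genes:

    R^2 = 1 - sum_{k,i in G} (pred(k) - s_i(k))^2
            / sum_{k,i in G} (s_i(k) - mean_k s_i(k))^2

and the adjusted value is ``R^2 - (1 - R^2) * |R| / (m - |R| - 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .sparse import SparseRepresentation, _path_coefficients

if TYPE_CHECKING:  # pragma: no cover
    from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Module",
    "predict_module",
    "fit_centroid",
    "select_sparsity_cv",
    "score_module",
    "module_r2",
    "adjusted_r2",
]


@dataclass(frozen=True)
class Module:
    """A discovered module: member genes, regulators, and coefficients."""

    module_id: str
    genes: tuple[str, ...]
    regulators: tuple[str, ...]
    coefficients: dict[str, float]
    cv_r2: float | None = None
    r2_train: float | None = None
    r2_test: float | None = None
    adj_r2_test: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "regulators", tuple(self.regulators))
        if set(self.regulators) != {r for r, a in self.coefficients.items() if a != 0}:
            raise ValueError(
                f"module {self.module_id!r}: regulator set must equal the "
                "non-zero coefficient support"
            )

    def scored(
        self,
        cv_r2: float | None = None,
        r2_train: float | None = None,
        r2_test: float | None = None,
        adj_r2_test: float | None = None,
    ) -> "Module":
        return Module(
            module_id=self.module_id,
            genes=self.genes,
            regulators=self.regulators,
            coefficients=self.coefficients,
            cv_r2=self.cv_r2 if cv_r2 is None else cv_r2,
            r2_train=self.r2_train if r2_train is None else r2_train,
            r2_test=self.r2_test if r2_test is None else r2_test,
            adj_r2_test=self.adj_r2_test if adj_r2_test is None else adj_r2_test,
        )


# -- scoring -------------------------------------------------------------------


def module_r2(
    member_values: np.ndarray,
    prediction: np.ndarray,
    convention: str = "gene_mean",
) -> float:
    """R^2 of one shared prediction against all member gene rows.

    ``member_values`` is (n_genes, m); ``prediction`` is (m,).  With the
    default ``gene_mean`` convention the total sum of squares is taken around
    each gene's across-sample mean.  The alternative ``sample_mean``
    convention centers on the per-sample mean across the member genes; note
    that for a prediction shared by all genes the numerator then decomposes
    as ``m*|G|*(pred - mean)^2 + SST``, so the score can never be positive —
    it is kept only for comparison.  Values are not clamped; a degenerate
    zero denominator falls back to the other centering so the score stays
    defined.
    """
    member_values = np.atleast_2d(np.asarray(member_values, dtype=float))
    prediction = np.asarray(prediction, dtype=float)
    sse = float(np.sum((member_values - prediction[None, :]) ** 2))
    row_centered = member_values - member_values.mean(axis=1, keepdims=True)
    col_centered = member_values - member_values.mean(axis=0, keepdims=True)
    if convention == "gene_mean":
        sst = float(np.sum(row_centered**2))
        alt = float(np.sum(col_centered**2))
    elif convention == "sample_mean":
        sst = float(np.sum(col_centered**2))
        alt = float(np.sum(row_centered**2))
    else:
        raise ValueError("convention must be 'gene_mean' or 'sample_mean'")
    if sst <= 1e-12:
        sst = alt
        if sst <= 1e-12:
            return 1.0 if sse <= 1e-12 else -np.inf
    return 1.0 - sse / sst


def adjusted_r2(r2: float, n_regulators: int, m: int) -> float:
    """Penalize R^2 for regulator count relative to sample count."""
    if m <= n_regulators + 1:
        raise ValueError(
            f"adjusted R^2 undefined for m={m} samples and "
            f"{n_regulators} regulators"
        )
    return r2 - (1.0 - r2) * n_regulators / (m - n_regulators - 1)


def predict_module(module: Module, x: "ExpressionMatrix") -> np.ndarray:
    """Shared predicted expression, one value per sample of ``x``."""
    pred = np.zeros(x.n_samples)
    gene_set = set(x.gene_ids)
    for r in module.regulators:
        if r not in gene_set:
            raise KeyError(f"regulator {r!r} missing from expression data")
        pred += module.coefficients[r] * x.row(r)
    return pred


def score_module(
    module: Module, x: "ExpressionMatrix", sample_ids=None
) -> tuple[float, float]:
    """(R^2, adjusted R^2) of a module on the given samples of ``x``."""
    if not module.genes:
        raise ValueError(f"module {module.module_id!r} has no genes")
    sub = x if sample_ids is None else x.subset(samples=list(sample_ids))
    pred = predict_module(module, sub)
    member = np.stack([sub.row(g) for g in module.genes])
    r2 = module_r2(member, pred)
    return r2, adjusted_r2(r2, len(module.regulators), sub.n_samples)


# -- centroid sparsification ---------------------------------------------------


def fit_centroid(
    centroid: np.ndarray,
    regulators: np.ndarray,
    c2: int,
    l2_penalty: float,
    refit: bool = False,
) -> SparseRepresentation:
    """Candidate p-sparse representations of a cluster centroid, p = 1..c2.

    Same contract as :func:`genemod.sparse.sparsify_gene` with ``c2`` as the
    sparsity budget.
    """
    from .sparse import sparsify_gene

    return sparsify_gene(
        centroid, regulators, c2, l2_penalty, gene_id="centroid", refit=refit
    )


def select_sparsity_cv(
    cluster_genes: np.ndarray,
    regulators: np.ndarray,
    c2: int,
    l2_penalty: float,
    n_folds: int = 10,
    seed: int = 0,
    refit: bool = True,
    tie_tolerance: float = 1e-3,
    return_scores: bool = False,
):
    """Choose the centroid sparsity by cross-validation over the cluster genes.

    Genes are shuffled into near-equal folds; per fold the centroid is the
    mean expression of the training-fold genes, candidate representations are
    fit along the elastic-net path (active sets refit by least squares when
    ``refit`` is set, the default), and each sparsity level is scored by the
    module R^2 on the held-out genes.  The level with the highest mean
    held-out R^2 wins; scores within ``tie_tolerance`` of the best count as
    tied and resolve to the smallest p (simplest-first parsimony).  Final
    coefficients are fit on the full-cluster centroid at that level.

    Returns ``(p, coefficients, cv_r2)`` (plus the per-level mean scores when
    ``return_scores`` is set).
    """
    cluster_genes = np.atleast_2d(np.asarray(cluster_genes, dtype=float))
    n_genes = cluster_genes.shape[0]
    if n_genes < 2:
        raise ValueError("cross-validation needs a cluster of >= 2 genes")
    folds = n_folds
    if folds > n_genes:
        logger.warning(
            "reducing %d folds to leave-one-out over %d genes", n_folds, n_genes
        )
        folds = n_genes
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_genes)
    fold_members = np.array_split(order, folds)
    design = np.asarray(regulators, dtype=float).T
    scores: dict[int, list[float]] = {p: [] for p in range(1, c2 + 1)}
    for held in fold_members:
        train = np.setdiff1d(order, held)
        centroid = cluster_genes[train].mean(axis=0)
        candidates = _path_coefficients(design, centroid, c2, l2_penalty, refit=refit)
        held_rows = cluster_genes[held]
        for p, coef in candidates.items():
            scores[p].append(module_r2(held_rows, design @ coef))
    mean_scores = {p: float(np.mean(v)) for p, v in scores.items()}
    top = max(mean_scores.values())
    best_p = min(p for p, s in mean_scores.items() if s >= top - tie_tolerance)
    final = _path_coefficients(
        design, cluster_genes.mean(axis=0), c2, l2_penalty, refit=refit
    )
    result = (best_p, final[best_p], mean_scores[best_p])
    if return_scores:
        return (*result, mean_scores)
    return result
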