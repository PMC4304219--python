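"""K-means on sparse coefficient vectors and expression centroids."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Mapping

import numpy as np
from sklearn.cluster import KMeans

if TYPE_CHECKING:  # pragma: no cover
    from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["ClusterAssignment", "cluster_sparse", "attach_expression_centroids"]


@dataclass(frozen=True)
class ClusterAssignment:
    """Gene-to-cluster labels with per-cluster centroids.

    ``labels`` maps gene IDs to cluster indices 1..k_effective.
    ``centroids_sparse[c]`` is the mean of the member sparse coefficient
    vectors of cluster c+1; ``centroids_expression`` (filled by
    :func:`attach_expression_centroids`) is the mean of member genes'
    normalized expression over the training samples.
    """

    labels: dict[str, int]
    centroids_sparse: np.ndarray
    centroids_expression: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return self.centroids_sparse.shape[0]

    def members(self, cluster: int) -> list[str]:
        return [g for g, c in self.labels.items() if c == cluster]


def cluster_sparse(
    reps: Mapping[str, np.ndarray], k: int, seed: int
) -> ClusterAssignment:
    """Standard Euclidean K-means over the sparse coefficient vectors.

    Deterministic given ``seed`` (k-means++ initialization, 10 restarts).  If
    the vectors contain fewer distinct points than ``k`` the cluster count is
    reduced with a warning.  Centroids are recomputed as exact member means.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    gene_ids = list(reps)
    if k > len(gene_ids):
        raise ValueError(f"k={k} exceeds the {len(gene_ids)} genes to cluster")
    points = np.stack([np.asarray(reps[g], dtype=float) for g in gene_ids])
    n_distinct = np.unique(points, axis=0).shape[0]
    k_eff = min(k, n_distinct)
    if k_eff < k:
        logger.warning(
            "only %d distinct points; clustering with k=%d instead of %d",
            n_distinct,
            k_eff,
            k,
        )
    km = KMeans(
        n_clusters=k_eff,
        init="k-means++",
        n_init=10,
        max_iter=300,
        tol=1e-6,
        random_state=seed,
    ).fit(points)
    raw = km.labels_
    # renumber to 1..k_eff in order of first appearance, drop empty clusters
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for gid, lab in zip(gene_ids, raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[gid] = remap[lab]
    centroids = np.stack(
        [
            points[[labels[g] == c for g in gene_ids]].mean(axis=0)
            for c in range(1, len(remap) + 1)
        ]
    )
    return ClusterAssignment(labels=labels, centroids_sparse=centroids)


def attach_expression_centroids(
    assign: ClusterAssignment, x: "ExpressionMatrix"
) -> ClusterAssignment:
    """Fill expression-space centroids: per-cluster mean of member gene rows."""
    rows = []
    for c in range(1, assign.n_clusters + 1):
        members = assign.members(c)
        if not members:
            logger.warning("cluster %d has no members; skipped", c)
            rows.append(np.full(x.n_samples, np.nan))
            continue
        rows.append(np.stack([x.row(g) for g in members]).mean(axis=0))
    return replace(assign, centroids_expression=np.stack(rows))
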