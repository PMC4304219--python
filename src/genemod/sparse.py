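"""p-sparse regulator representations of genes via the elastic-net path.

Every gene is approximated by linear combinations of 1..C1 regulators.  The
representation at sparsity p is read off the L1 regularization path: with the
L2 penalty held fixed, the path is walked from the strongest L1 penalty
downward and the coefficient vector at the first breakpoint with exactly p
active regulators is recorded.  The fixed-L2 path is obtained exactly as a
LARS/lasso path on the row-augmented design ([X; sqrt(l2) I], [y; 0]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
from sklearn.linear_model import lars_path

if TYPE_CHECKING:  # pragma: no cover
    from .io import ExpressionMatrix

__all__ = ["SparseRepresentation", "sparsify_gene", "sparsify_all"]


@dataclass(frozen=True)
class SparseRepresentation:
    """Family of p-sparse coefficient vectors over the regulator basis.

    ``reps[p]`` has at most p non-zero entries; ``fit_r2[p]`` is the training
    R^2 of that representation against the gene's true expression.
    """

    gene_id: str
    reps: dict[int, np.ndarray]
    fit_r2: dict[int, float]


def _path_coefficients(
    design: np.ndarray,
    target: np.ndarray,
    max_active: int,
    l2_penalty: float,
    refit: bool = False,
) -> dict[int, np.ndarray]:
    """Coefficient vector at each sparsity level 1..max_active.

    Walks the lasso path of the augmented design (equivalent to the fixed-L2
    elastic-net path).  Where the path skips or never reaches a level p, the
    densest earlier breakpoint with <= p active variables is reused.  With
    ``refit`` the active set of each level is refit by unpenalized least
    squares on the original design.
    """
    n_features = design.shape[1]
    raw_design, raw_target = design, target
    if l2_penalty > 0:
        design = np.vstack([design, np.sqrt(l2_penalty) * np.eye(n_features)])
        target = np.concatenate([target, np.zeros(n_features)])
    _, _, coefs = lars_path(
        design,
        target,
        method="lasso",
        max_iter=max(8 * max_active, 50),
    )
    counts = np.count_nonzero(coefs, axis=0)
    first_at: dict[int, np.ndarray] = {}
    for j in range(coefs.shape[1]):
        c = int(counts[j])
        if 0 < c <= max_active and c not in first_at:
            first_at[c] = coefs[:, j].copy()
    out: dict[int, np.ndarray] = {}
    best: np.ndarray | None = None
    for p in range(1, max_active + 1):
        if p in first_at:
            best = first_at[p]
        if best is None:
            # path produced nothing below p yet (multi-entry first step);
            # fall back to the sparsest breakpoint available
            reached = min(first_at) if first_at else None
            best = first_at[reached] if reached else np.zeros(n_features)
        out[p] = best
    if refit:
        for p, coef in out.items():
            support = np.flatnonzero(coef)
            if support.size:
                ls, *_ = np.linalg.lstsq(raw_design[:, support], raw_target, rcond=None)
                refitted = np.zeros(n_features)
                refitted[support] = ls
                out[p] = refitted
    return out


def _fit_r2(gene: np.ndarray, design: np.ndarray, coef: np.ndarray) -> float:
    resid = gene - design @ coef
    sst = float(np.sum((gene - gene.mean()) ** 2))
    return 1.0 - float(resid @ resid) / sst


def sparsify_gene(
    gene: np.ndarray,
    regulators: np.ndarray,
    c1: int,
    l2_penalty: float,
    gene_id: str = "gene",
    refit: bool = False,
) -> SparseRepresentation:
    """Express one gene as 1..c1 regulators via the elastic-net path.

    Parameters
    ----------
    gene : ndarray of shape (m,)
        Normalized expression over the training samples.
    regulators : ndarray of shape (n_regulators, m)
        Normalized regulator expression rows (the gene itself excluded).
    c1 : int
        Maximum number of regulators; must be < ``n_regulators``.
    l2_penalty : float
        Fixed L2 penalty of the elastic net (0 gives the plain lasso path).
    """
    gene = np.asarray(gene, dtype=float)
    regulators = np.asarray(regulators, dtype=float)
    n_reg = regulators.shape[0]
    if c1 < 1:
        raise ValueError("c1 must be >= 1")
    if c1 >= n_reg:
        raise ValueError(f"c1={c1} must be smaller than the {n_reg} regulators")
    if l2_penalty < 0:
        raise ValueError("l2_penalty must be nonnegative")
    if np.allclose(gene, gene[0]):
        raise ValueError(f"zero-variance gene {gene_id!r} cannot be sparsified")
    design = regulators.T  # samples x regulators
    reps = _path_coefficients(design, gene, c1, l2_penalty, refit=refit)
    fit = {p: _fit_r2(gene, design, coef) for p, coef in reps.items()}
    return SparseRepresentation(gene_id=gene_id, reps=reps, fit_r2=fit)


def sparsify_all(
    x: "ExpressionMatrix",
    gene_ids: Iterable[str],
    c1: int,
    l2_penalty: float,
) -> dict[str, SparseRepresentation]:
    """Sparsify every requested gene over the matrix's regulator basis.

    Each gene is handled independently (result is order-invariant).  A gene
    that is itself a regulator is excluded from its own basis; its coefficient
    vector keeps the full basis length with a structural zero at itself.  When
    the usable basis is too small for ``c1``, the per-gene budget is capped at
    basis size − 1 and the upper sparsity levels repeat the densest one, so
    ``reps`` always carries keys 1..c1.
    """
    reg_ids = x.regulator_ids
    if not reg_ids:
        raise ValueError("matrix has no regulator-flagged genes")
    reg_pos = {r: i for i, r in enumerate(reg_ids)}
    basis = np.stack([x.row(r) for r in reg_ids])
    out: dict[str, SparseRepresentation] = {}
    for gid in gene_ids:
        gene = x.row(gid)
        try:
            if gid in reg_pos:
                keep = [i for i in range(len(reg_ids)) if i != reg_pos[gid]]
                c1_eff = min(c1, len(keep) - 1)
                if c1_eff < 1:
                    raise ValueError("fewer than 2 usable regulators")
                rep = sparsify_gene(gene, basis[keep], c1_eff, l2_penalty, gene_id=gid)
                rep = SparseRepresentation(
                    gene_id=gid,
                    reps={p: _embed(v, keep, len(reg_ids)) for p, v in rep.reps.items()},
                    fit_r2=rep.fit_r2,
                )
            else:
                c1_eff = min(c1, len(reg_ids) - 1)
                if c1_eff < 1:
                    raise ValueError("fewer than 2 usable regulators")
                rep = sparsify_gene(gene, basis, c1_eff, l2_penalty, gene_id=gid)
            if c1_eff < c1:
                reps = dict(rep.reps)
                fit = dict(rep.fit_r2)
                for p in range(c1_eff + 1, c1 + 1):
                    reps[p] = reps[c1_eff]
                    fit[p] = fit[c1_eff]
                rep = SparseRepresentation(gene_id=gid, reps=reps, fit_r2=fit)
        except ValueError as exc:
            raise ValueError(f"gene {gid!r}: {exc}") from exc
        out[gid] = rep
    return out


def _embed(coef: np.ndarray, keep: list[int], size: int) -> np.ndarray:
    full = np.zeros(size)
    full[keep] = coef
    return full


def dump_representations(
    reps: Mapping[str, SparseRepresentation],
    regulator_ids: Iterable[str],
    path: str,
) -> None:
    """Debug TSV of all non-zero path coefficients."""
    reg_ids = list(regulator_ids)
    lines = ["gene_id\tp\tregulator_id\tcoefficient"]
    for gid, rep in reps.items():
        for p, coef in sorted(rep.reps.items()):
            for idx in np.flatnonzero(coef):
                lines.append(f"{gid}\t{p}\t{reg_ids[idx]}\t{coef[idx]:.17g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
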