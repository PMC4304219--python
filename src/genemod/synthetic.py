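"""Synthetic expression matrices with planted module structure.

Regulator rows are independent standard normals over samples.  Each planted
module draws a regulator subset and shared coefficients; every member gene is
the coefficient-weighted regulator sum plus independent Gaussian noise.
Background genes are pure noise.  All rows are z-normalized, so generated
matrices are directly usable by the discovery loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .centroid import Module
from .io import ExpressionMatrix
from .metrics import jaccard

__all__ = [
    "PlantedDesign",
    "PlantedModule",
    "PlantedTruth",
    "RecoveryScore",
    "generate",
    "score_recovery",
]


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of one synthetic dataset."""

    n_regulators: int = 40
    n_modules: int = 10
    regulators_per_module: tuple[int, int] = (2, 4)
    genes_per_module: tuple[int, int] = (20, 20)
    n_background_genes: int = 100
    noise_sd: float = 0.2
    coefficient_range: tuple[float, float] = (0.5, 1.5)
    m_samples: int = 200
    seed: int = 0
    nonnegative: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.regulators_per_module
        if not 1 <= lo <= hi:
            raise ValueError("bad regulators_per_module range")
        if hi > self.n_regulators:
            raise ValueError("regulators_per_module max exceeds n_regulators")
        glo, ghi = self.genes_per_module
        if not 1 <= glo <= ghi:
            raise ValueError("bad genes_per_module range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        clo, chi = self.coefficient_range
        if not 0 < clo <= chi:
            raise ValueError("coefficient_range must be positive and ordered")
        if self.m_samples < 4:
            raise ValueError("m_samples must be >= 4")


@dataclass(frozen=True)
class PlantedModule:
    module_id: str
    gene_ids: tuple[str, ...]
    regulator_ids: tuple[str, ...]
    coefficients: tuple[float, ...]


@dataclass(frozen=True)
class PlantedTruth:
    modules: tuple[PlantedModule, ...]
    background_gene_ids: tuple[str, ...]


def _znorm(rows: np.ndarray) -> np.ndarray:
    mean = rows.mean(axis=1, keepdims=True)
    sd = rows.std(axis=1, ddof=1, keepdims=True)
    return (rows - mean) / sd


def generate(design: PlantedDesign) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Draw one planted-module expression matrix, reproducible from the seed."""
    rng = np.random.default_rng(design.seed)
    m = design.m_samples
    # normalize the basis first so truth coefficients refer to the emitted rows
    reg_values = _znorm(rng.standard_normal((design.n_regulators, m)))
    reg_ids = [f"R{i + 1:04d}" for i in range(design.n_regulators)]

    gene_rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    planted: list[PlantedModule] = []
    rlo, rhi = design.regulators_per_module
    glo, ghi = design.genes_per_module
    clo, chi = design.coefficient_range
    for k in range(design.n_modules):
        n_r = int(rng.integers(rlo, rhi + 1))
        n_g = int(rng.integers(glo, ghi + 1))
        reg_idx = rng.choice(design.n_regulators, size=n_r, replace=False)
        coefs = rng.uniform(clo, chi, size=n_r)
        if not design.nonnegative:
            coefs *= rng.choice([-1.0, 1.0], size=n_r)
        signal = coefs @ reg_values[reg_idx]
        ids = [f"M{k + 1:02d}_G{i + 1:03d}" for i in range(n_g)]
        noise = design.noise_sd * rng.standard_normal((n_g, m))
        gene_rows.append(signal[None, :] + noise)
        gene_ids.extend(ids)
        planted.append(
            PlantedModule(
                module_id=f"planted{k + 1:02d}",
                gene_ids=tuple(ids),
                regulator_ids=tuple(reg_ids[i] for i in reg_idx),
                coefficients=tuple(float(c) for c in coefs),
            )
        )
    background_ids = [f"B{i + 1:04d}" for i in range(design.n_background_genes)]
    if design.n_background_genes:
        gene_rows.append(rng.standard_normal((design.n_background_genes, m)))
        gene_ids.extend(background_ids)

    values = np.vstack([reg_values, *gene_rows])
    all_ids = reg_ids + gene_ids
    flags = np.zeros(len(all_ids), dtype=bool)
    flags[: design.n_regulators] = True
    x = ExpressionMatrix(
        gene_ids=tuple(all_ids),
        sample_ids=tuple(f"S{j + 1:04d}" for j in range(m)),
        values=_znorm(values),
        regulator_flags=flags,
    )
    return x, PlantedTruth(
        modules=tuple(planted), background_gene_ids=tuple(background_ids)
    )


@dataclass(frozen=True)
class RecoveryScore:
    mean_gene_jaccard: float
    regulator_precision: float
    regulator_recall: float
    per_module: tuple[float, ...] = field(default=())


def score_recovery(
    discovered: Sequence[Module], truth: PlantedTruth
) -> RecoveryScore:
    """Match each planted module to its best-Jaccard discovered module.

    The gene-set Jaccard of the best match is averaged over planted modules;
    regulator precision and recall are computed on the matched pairs and
    averaged (a matched module with no regulators scores precision 0).
    """
    jaccards: list[float] = []
    precisions: list[float] = []
    recalls: list[float] = []
    for pm in truth.modules:
        if not discovered:
            jaccards.append(0.0)
            precisions.append(0.0)
            recalls.append(0.0)
            continue
        best = max(discovered, key=lambda m: jaccard(m.genes, pm.gene_ids))
        jaccards.append(jaccard(best.genes, pm.gene_ids))
        true_r = set(pm.regulator_ids)
        found_r = set(best.regulators)
        hit = len(true_r & found_r)
        precisions.append(hit / len(found_r) if found_r else 0.0)
        recalls.append(hit / len(true_r))
    return RecoveryScore(
        mean_gene_jaccard=float(np.mean(jaccards)),
        regulator_precision=float(np.mean(precisions)),
        regulator_recall=float(np.mean(recalls)),
        per_module=tuple(jaccards),
    )
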