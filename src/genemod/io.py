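"""Expression-matrix I/O, preprocessing, and train/test split protocol.

Expression matrices are tab-separated text: header row ``gene_id<TAB>sample1
<TAB>...``, one gene per row.  Regulator lists are plain text, one gene ID per
line.  Module files are a long-format TSV (``module_id, role, member_id,
coefficient``) with an optional companion summary TSV carrying fit scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .centroid import Module

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "BootstrapSplit",
    "read_expression",
    "write_expression",
    "read_regulators",
    "write_regulators",
    "normalize_genes",
    "variance_filter",
    "make_splits",
    "write_modules",
    "read_modules",
    "write_summary",
    "write_gmt",
]

TRAIN_FRACTION = 0.7


class FormatError(ValueError):
    """Malformed input file (duplicate ID, non-numeric cell, bad role...)."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples real-valued expression with a regulator flag per gene.

    Parameters
    ----------
    gene_ids : tuple of str
        Ordered, unique row identifiers.
    sample_ids : tuple of str
        Ordered, unique column identifiers.
    values : ndarray of shape (n_genes, n_samples)
        Finite real expression values.
    regulator_flags : ndarray of bool, shape (n_genes,)
        True for genes allowed on the right-hand side of module regressions.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    regulator_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if self.regulator_flags is None:
            flags = np.zeros(len(self.gene_ids), dtype=bool)
        else:
            flags = np.asarray(self.regulator_flags, dtype=bool)
        object.__setattr__(self, "regulator_flags", flags)
        self._validate()

    def _validate(self) -> None:
        n, m = len(self.gene_ids), len(self.sample_ids)
        if self.values.shape != (n, m):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} genes x {m} samples"
            )
        if self.regulator_flags.shape != (n,):
            raise ValueError("regulator_flags length does not match gene count")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
                raise FormatError(f"duplicate {name} ID: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def regulator_ids(self) -> tuple[str, ...]:
        return tuple(g for g, f in zip(self.gene_ids, self.regulator_flags) if f)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_lookup[gene_id]
        except AttributeError:
            lookup = {g: i for i, g in enumerate(self.gene_ids)}
            object.__setattr__(self, "_gene_lookup", lookup)
            return lookup[gene_id]

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        return np.array([pos[s] for s in sample_ids], dtype=int)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def subset(
        self,
        genes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        """Restrict to the given genes and/or samples (keeping their order)."""
        gi = (
            np.arange(self.n_genes)
            if genes is None
            else np.array([self.gene_index(g) for g in genes], dtype=int)
        )
        si = (
            np.arange(self.n_samples)
            if samples is None
            else self.sample_indices(samples)
        )
        return ExpressionMatrix(
            gene_ids=tuple(self.gene_ids[i] for i in gi),
            sample_ids=tuple(self.sample_ids[j] for j in si),
            values=self.values[np.ix_(gi, si)],
            regulator_flags=self.regulator_flags[gi],
        )

    def with_regulators(self, regulator_ids: Iterable[str]) -> "ExpressionMatrix":
        """Return a copy flagging the given genes as regulators.

        IDs absent from the matrix are reported and ignored with a warning.
        """
        wanted = list(regulator_ids)
        present = set(self.gene_ids)
        missing = [r for r in wanted if r not in present]
        if missing:
            logger.warning(
                "%d regulator IDs not in matrix, ignored: %s%s",
                len(missing),
                ", ".join(missing[:5]),
                "..." if len(missing) > 5 else "",
            )
        keep = set(wanted) - set(missing)
        flags = np.array([g in keep for g in self.gene_ids], dtype=bool)
        return replace(self, regulator_flags=flags)


@dataclass(frozen=True)
class BootstrapSplit:
    """One random 70/30 train/test partition of the samples."""

    train_sample_ids: tuple[str, ...]
    test_sample_ids: tuple[str, ...]
    seed: int
    index: int

    def __post_init__(self) -> None:
        train, test = set(self.train_sample_ids), set(self.test_sample_ids)
        if train & test:
            raise ValueError("train and test samples overlap")


# -- readers -------------------------------------------------------------------


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV into an :class:`ExpressionMatrix`.

    First row holds sample IDs, first column gene IDs.  Duplicated IDs and
    non-numeric cells raise :class:`FormatError` naming the offender.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen: set[str] = set()
    for name in header[1:]:  # pandas would silently rename duplicate columns
        if name in seen:
            raise FormatError(f"duplicate sample ID: {name!r}")
        seen.add(name)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    sample_ids = header[1:]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy() | df.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"non-numeric cell {df.iat[i, j]!r} at gene {gene_ids[i]!r}, "
            f"sample {sample_ids[j]!r} in {path}"
        )
    return ExpressionMatrix(
        gene_ids=tuple(gene_ids),
        sample_ids=tuple(sample_ids),
        values=numeric.to_numpy(dtype=float),
    )


def write_expression(x: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the same TSV layout :func:`read_expression` reads."""
    df = pd.DataFrame(x.values, index=list(x.gene_ids), columns=list(x.sample_ids))
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_regulators(regulator_ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(regulator_ids) + "\n")


def read_regulators(path: str | Path) -> list[str]:
    """Read a one-ID-per-line regulator list (blank lines ignored)."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        token = line.strip()
        if token:
            out.append(token)
    return out


# -- preprocessing -------------------------------------------------------------


def normalize_genes(
    x: ExpressionMatrix, sample_ids: Sequence[str] | None = None
) -> ExpressionMatrix:
    """Scale every gene row to mean 0 and sample standard deviation 1.

    The (m-1)-denominator standard deviation is used.  When ``sample_ids`` is
    given, mean and sd are estimated on those samples only (train-only
    normalization) but applied to every column; the default estimates on all
    samples.  A constant gene raises ``ValueError`` naming it.
    """
    cols = (
        np.arange(x.n_samples)
        if sample_ids is None
        else x.sample_indices(sample_ids)
    )
    ref = x.values[:, cols]
    mean = ref.mean(axis=1, keepdims=True)
    sd = ref.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(f"constant gene cannot be normalized: {x.gene_ids[flat[0]]!r}")
    return replace(x, values=(x.values - mean) / sd)


def variance_filter(
    x: ExpressionMatrix, fraction: float, split: BootstrapSplit
) -> list[str]:
    """IDs of the ``max(1, floor(fraction * n))`` most train-variable genes.

    Variance is computed on the split's training samples only.  Ties at the
    cutoff keep the gene earlier in input order; the returned list preserves
    input order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not split.train_sample_ids:
        raise ValueError("empty training set")
    cols = x.sample_indices(split.train_sample_ids)
    var = x.values[:, cols].var(axis=1, ddof=1)
    k = max(1, math.floor(fraction * x.n_genes))
    order = np.argsort(-var, kind="stable")  # stable: ties keep input order
    chosen = np.sort(order[:k])
    return [x.gene_ids[i] for i in chosen]


def make_splits(
    x: ExpressionMatrix, n_bootstraps: int, base_seed: int
) -> list[BootstrapSplit]:
    """Draw ``n_bootstraps`` random 70/30 sample splits, split i seeded with
    ``base_seed + i``."""
    if n_bootstraps < 1:
        raise ValueError("n_bootstraps must be >= 1")
    if x.n_samples < 4:
        raise ValueError("need at least 4 samples to split 70/30")
    if n_bootstraps < 2:
        logger.warning("consistency estimation needs >= 2 bootstraps")
    n_train = round(TRAIN_FRACTION * x.n_samples)
    splits = []
    for i in range(1, n_bootstraps + 1):
        rng = np.random.default_rng(base_seed + i)
        perm = rng.permutation(x.n_samples)
        splits.append(
            BootstrapSplit(
                train_sample_ids=tuple(x.sample_ids[j] for j in perm[:n_train]),
                test_sample_ids=tuple(x.sample_ids[j] for j in perm[n_train:]),
                seed=base_seed + i,
                index=i,
            )
        )
    return splits


# -- module files --------------------------------------------------------------

_MODULE_HEADER = "module_id\trole\tmember_id\tcoefficient"
_SUMMARY_HEADER = (
    "module_id\tn_genes\tn_regulators\tcv_r2\tr2_train\tr2_test\tadj_r2_test"
)


def _fmt(v: float | None) -> str:
    return "" if v is None else format(float(v), ".17g")


def write_modules(
    modules: Sequence[Module],
    path: str | Path,
    summary_path: str | Path | None = None,
) -> None:
    """Write modules as a long TSV; optionally a companion score summary."""
    lines = [_MODULE_HEADER]
    for mod in modules:
        for g in mod.genes:
            lines.append(f"{mod.module_id}\tgene\t{g}\t")
        for r in mod.regulators:
            lines.append(f"{mod.module_id}\tregulator\t{r}\t{_fmt(mod.coefficients[r])}")
    Path(path).write_text("\n".join(lines) + "\n")
    if summary_path is not None:
        write_summary(modules, summary_path)


def write_summary(modules: Sequence[Module], path: str | Path) -> None:
    lines = [_SUMMARY_HEADER]
    for mod in modules:
        lines.append(
            "\t".join(
                [
                    mod.module_id,
                    str(len(mod.genes)),
                    str(len(mod.regulators)),
                    _fmt(mod.cv_r2),
                    _fmt(mod.r2_train),
                    _fmt(mod.r2_test),
                    _fmt(mod.adj_r2_test),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_modules(
    path: str | Path, summary_path: str | Path | None = None
) -> list[Module]:
    """Read a long-format module TSV back (scores from the summary if given)."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _MODULE_HEADER:
        raise FormatError(f"bad module file header in {path}")
    genes: dict[str, list[str]] = {}
    coeffs: dict[str, dict[str, float]] = {}
    order: list[str] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}:{ln}: expected 4 columns")
        mid, role, member, coef = parts
        if mid not in genes:
            genes[mid] = []
            coeffs[mid] = {}
            order.append(mid)
        if role == "gene":
            genes[mid].append(member)
        elif role == "regulator":
            try:
                value = float(coef)
            except ValueError:
                raise FormatError(
                    f"{path}:{ln}: bad coefficient {coef!r}"
                ) from None
            if value == 0:
                raise FormatError(
                    f"{path}:{ln}: regulator {member!r} has zero coefficient "
                    f"but is listed in module {mid!r}"
                )
            coeffs[mid][member] = value
        else:
            raise FormatError(f"{path}:{ln}: unknown role token {role!r}")
    scores: dict[str, dict[str, float | None]] = {}
    if summary_path is not None:
        scores = _read_summary(summary_path)
    out = []
    for mid in order:
        s = scores.get(mid, {})
        out.append(
            Module(
                module_id=mid,
                genes=tuple(genes[mid]),
                regulators=tuple(coeffs[mid]),
                coefficients=dict(coeffs[mid]),
                cv_r2=s.get("cv_r2"),
                r2_train=s.get("r2_train"),
                r2_test=s.get("r2_test"),
                adj_r2_test=s.get("adj_r2_test"),
            )
        )
    return out


def _read_summary(path: str | Path) -> dict[str, dict[str, float | None]]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _SUMMARY_HEADER:
        raise FormatError(f"bad summary header in {path}")
    fields = _SUMMARY_HEADER.split("\t")
    out: dict[str, dict[str, float | None]] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        rec = dict(zip(fields, line.split("\t")))
        out[rec["module_id"]] = {
            k: (float(rec[k]) if rec.get(k) else None)
            for k in ("cv_r2", "r2_train", "r2_test", "adj_r2_test")
        }
    return out


def write_gmt(
    modules: Sequence[Module], path: str | Path, description: str = "genemod"
) -> None:
    """Export member gene sets in GMT format for interoperability."""
    lines = [
        "\t".join([mod.module_id, description, *mod.genes]) for mod in modules
    ]
    Path(path).write_text("\n".join(lines) + "\n")
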