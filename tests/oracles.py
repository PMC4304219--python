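"""Independent brute-force implementations used as test oracles.

Everything here is written with explicit loops and elementary formulas,
deliberately sharing no code with the package under test.
"""

import itertools
import math


def oracle_jaccard(a, b):
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    inter = sum(1 for x in a if x in b)
    union = len(a) + len(b) - inter
    return inter / union


def oracle_avg_module_jaccard(m1, m2):
    return (
        oracle_jaccard(m1.genes, m2.genes)
        + oracle_jaccard(m1.regulators, m2.regulators)
    ) / 2.0


def oracle_consistency(module_sets):
    pair_scores = []
    for a in range(len(module_sets)):
        for b in range(a + 1, len(module_sets)):
            vals = []
            for ma in module_sets[a]:
                vals.append(max(oracle_avg_module_jaccard(ma, mb) for mb in module_sets[b]))
            for mb in module_sets[b]:
                vals.append(max(oracle_avg_module_jaccard(mb, ma) for ma in module_sets[a]))
            pair_scores.append(sum(vals) / len(vals))
    return sum(pair_scores) / len(pair_scores)


def oracle_pearson(u, v):
    m = len(u)
    mu = sum(u) / m
    mv = sum(v) / m
    num = sum((u[k] - mu) * (v[k] - mv) for k in range(m))
    du = math.sqrt(sum((u[k] - mu) ** 2 for k in range(m)))
    dv = math.sqrt(sum((v[k] - mv) ** 2 for k in range(m)))
    return num / (du * dv)


def oracle_module_homogeneity(rows):
    """Mean over genes of the mean correlation with every other gene."""
    n = len(rows)
    per_gene = []
    for i in range(n):
        vals = [oracle_pearson(rows[i], rows[j]) for j in range(n) if j != i]
        per_gene.append(sum(vals) / len(vals))
    return sum(per_gene) / n


def oracle_homogeneity(module_rows):
    vals = [oracle_module_homogeneity(rows) for rows in module_rows]
    return sum(vals) / len(vals)


def oracle_module_r2(member_rows, prediction, convention="gene_mean"):
    """Printed-formula R^2 with explicit double loops, both centerings."""
    n = len(member_rows)
    m = len(prediction)
    sse = 0.0
    for i in range(n):
        for k in range(m):
            sse += (prediction[k] - member_rows[i][k]) ** 2
    sst = 0.0
    if convention == "gene_mean":
        for i in range(n):
            mean_i = sum(member_rows[i]) / m
            for k in range(m):
                sst += (member_rows[i][k] - mean_i) ** 2
    else:
        for k in range(m):
            mean_k = sum(member_rows[i][k] for i in range(n)) / n
            for i in range(n):
                sst += (member_rows[i][k] - mean_k) ** 2
    return 1.0 - sse / sst


def oracle_adjusted_r2(r2, n_regulators, m):
    return r2 - (1.0 - r2) * n_regulators / (m - n_regulators - 1)


def oracle_best_single_regulator(gene, regulators):
    """Index of the regulator with maximal squared correlation."""
    best, best_val = None, -1.0
    for j, reg in enumerate(regulators):
        rho = oracle_pearson(list(gene), list(reg)) ** 2
        if rho > best_val:
            best, best_val = j, rho
    return best


def oracle_best_pair(gene, regulators):
    """Active pair minimizing least-squares error, by exhaustive search."""
    import numpy as np

    gene = np.asarray(gene)
    best, best_err = None, float("inf")
    for i, j in itertools.combinations(range(len(regulators)), 2):
        design = np.column_stack([regulators[i], regulators[j]])
        coef, *_ = np.linalg.lstsq(design, gene, rcond=None)
        err = float(np.sum((gene - design @ coef) ** 2))
        if err < best_err:
            best, best_err = (i, j), err
    return set(best)


def oracle_variance_topk(rows, k):
    """Indices of the k most variable rows (sample variance, ties to earlier)."""
    n = len(rows)
    m = len(rows[0])
    var = []
    for i in range(n):
        mu = sum(rows[i]) / m
        var.append(sum((v - mu) ** 2 for v in rows[i]) / (m - 1))
    order = sorted(range(n), key=lambda i: (-var[i], i))
    return sorted(order[:k])


def oracle_reporting_prefix(modules, min_genes, max_genes, coverage):
    """Shortest adj-R^2-ranked prefix reaching the coverage, by enumeration."""
    sized = [m for m in modules if min_genes <= len(m.genes) <= max_genes]
    if not sized:
        return []
    universe = set()
    for m in sized:
        universe |= set(m.genes)
    ranked = sorted(sized, key=lambda m: -m.adj_r2_test)
    for length in range(1, len(ranked) + 1):
        covered = set()
        for m in ranked[:length]:
            covered |= set(m.genes)
        if len(covered) >= coverage * len(universe):
            return ranked[:length]
    return ranked
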