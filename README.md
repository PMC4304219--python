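# genemod

Iterative discovery of gene **modules**: clusters of genes whose expression is
well approximated by one shared sparse linear combination of a few *regulator*
genes (e.g. transcription factors), plus the evaluation protocol that goes
with it (adjusted R², bootstrap consistency via Jaccard matching, homogeneity)
and a planted-module synthetic generator for verification.

## How it works

Given a z-normalized genes × samples expression matrix and a list of
regulator gene IDs, each iteration:

1. **Gene sparsification** — every remaining gene is expressed as a linear
   combination of 1..C₁ regulators along the elastic-net regularization path
   (fixed L₂ penalty, decreasing L₁; computed exactly via a LARS path on the
   row-augmented design).
2. **K-means** — genes are clustered by their S₁-sparse coefficient vectors
   (Euclidean distance in regulator-basis space, k-means++ seeding).
3. **Centroid sparsification** — each cluster's expression centroid is
   expressed with 1..C₂ regulators; the sparsity level is chosen by 10-fold
   cross-validation over the cluster's *genes*, and the cluster is scored by
   the held-out module R².
4. **Filtering** — the union of the top-P% clusters by CV R² and the clusters
   exceeding `r_thresh` within the `[n_min, n_max]` size window become final
   modules; everything else carries into the next iteration with S₁ + 2,
   until the sparsity budget, gene pool, or iteration cap runs out.

Evaluation follows random 70/30 train/test bootstraps: modules are discovered
on the training samples and scored on both splits; consistency S matches
module sets across bootstraps by average gene/regulator Jaccard; the
reporting filter keeps 5–1000-gene modules ranked by adjusted R² until ≥ 80%
gene coverage.

## CLI

```sh
# write a planted-module dataset (expression.tsv, regulators.txt, truth.tsv)
genemod simulate --out-dir sim/ --seed 1

# discover modules over 3 bootstraps
genemod run --expression sim/expression.tsv --regulators sim/regulators.txt \
    --out-dir out/ --bootstraps 3 --seed 1

# aggregate metrics (adjusted R², consistency, homogeneity, ...)
genemod evaluate --modules out/modules_b1.tsv --modules out/modules_b2.tsv \
    --modules out/modules_b3.tsv --expression sim/expression.tsv --out metrics.tsv

# greedy single-parameter tuning over a YAML grid, e.g. "k: [10, 20, 50]"
genemod tune --expression sim/expression.tsv --regulators sim/regulators.txt \
    --grid grid.yaml --out tuned.yaml
```

Configuration files are flat YAML with the fields of `CamodiConfig`
(`c1`, `c2`, `s1_init`, `s1_step`, `k`, `p_keep`, `r_thresh`, `n_min`,
`n_max`, `l2_gene`, `l2_centroid`, `n_folds`, `max_iterations`, `base_seed`,
`k_scaling`, `variance_fraction`, `normalize_train_only`).

## File formats

- **Expression matrix**: TSV, header `gene_id<TAB>sample1<TAB>...`, one gene
  per row.
- **Regulator list**: plain text, one gene ID per line.
- **Module file**: long TSV (`module_id, role, member_id, coefficient`) plus a
  companion summary TSV (`module_id, n_genes, n_regulators, cv_r2, r2_train,
  r2_test, adj_r2_test`); GMT export available for interoperability.

## Python API

```python
import genemod as gm

x, truth = gm.generate(gm.PlantedDesign(seed=1))
config = gm.CamodiConfig(c1=6, c2=6, k=15, base_seed=1)
results = gm.run_bootstraps(x, config, n_bootstraps=3)

print(gm.consistency(results))
print(gm.score_recovery(list(results[0].modules), truth))
```
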