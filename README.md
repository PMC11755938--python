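# rviskit

Gene-level mutational constraint analysis for population variant
catalogs, built around the Residual Variation Intolerance Score (RVIS).
It is aimed at comparative and population geneticists who want to ask,
for a non-human catalog such as a macaque cohort: *which genes tolerate
common functional variation, which do not, and do disease gene lists
cluster among the intolerant ones?*

## What it computes

**Constraint score.** For each gene, let `X` be the total number of
protein-coding variants (missense + loss-of-function + synonymous) and
`Y` the number of *common functional* variants (missense/LoF with
allele frequency ≥ a MAF threshold, default 0.1%). Across all genes the
package fits ordinary least squares

```
Y_g = α + β·X_g + ε_g
```

and takes the externally studentized residual of each gene —
`ε̂_g / (s₍₋g₎·√(1−h_g))`, with `h_g` the leverage and `s₍₋g₎` the
leave-one-out residual standard error — re-centered to mean 0, as its
RVIS. Scores below zero mean fewer common functional variants than the
gene's mutational burden predicts: constraint. Genes scoring above a
one-sided outlier cutoff (default +11, the convention that removes
hypervariable genes such as *MUC16*) are excluded and the model refit
once.

**Downstream statistics.**

* Welch unequal-variance t-test of a gene set vs the background genome,
  and a univariate logistic regression of set membership on RVIS whose
  `exp(β)` is an odds ratio per unit of score (constrained sets give
  OR < 1).
* Pearson correlation between two species' score tables over the inner
  gene join, with a Fisher-z 95% CI.
* Unweighted Kolmogorov–Smirnov gene-set enrichment over the ascending
  RVIS ranking (hit +1/Nh, miss −1/(N−Nh); ES = signed extremum of the
  running sum) with a permutation null, and a hypergeometric
  over-representation test within the top-2% constrained tail
  (`floor(N × 0.02)` genes — 363 for an 18,166-gene universe).
* Chain-file (UCSC format) point liftover of predicted-damaging
  variants, exact-allele intersection with disease-variant catalogs,
  per-set damaged-gene proportions, and CADD-ranked variant tables.

A seeded synthetic-catalog generator (`rviskit.synthetic`) produces
complete input bundles — VCF, gene models, gene sets, disease variants,
damaging-variant table, chain file — with known per-gene ground truth,
so every stage can be exercised and validated end to end.

## Worked example

```python
import tempfile
import rviskit as rk
from rviskit.synthetic import read_gene_models

config = rk.SimConfig(n_genes=500, seed=42)         # 25% constrained genes
bundle = rk.generate_catalog(config, tempfile.mkdtemp())

records = list(rk.read_catalog(bundle.vcf))
retained, _ = rk.qc_filter(records)                  # QUAL>=30, DP 10..50, SNV, autosome
counts = rk.count_gene_variants(retained, read_gene_models(bundle.gene_models))
scores = rk.remove_outliers(rk.compute_rvis(counts)).scores()

asd = rk.GeneSet.from_file(bundle.gene_sets["ASD"])
print(rk.gene_set_constraint_test(scores, asd))
```

prints (seed 42):

```
GroupTestResult(set_name='ASD', n_set=22, mean_set=-1.25, ...
                t_statistic=-5.68, p_value=9.4e-06, odds_ratio=0.35, ...)
```

The synthetic ASD set was drawn preferentially from constrained genes,
so its mean score sits 1.3 units below the background, the t-test is
strongly significant, and the odds ratio is well below 1 — the same
signature that curated neurodevelopmental gene lists show on real
catalogs. The scripts in `examples/` walk through each capability
(simulation, QC, scoring, set statistics, enrichment, liftover overlap)
and print annotated output.

A thin CLI mirrors the stages for shell use:

```bash
rviskit simulate --out bundle --seed 3
rviskit qc --vcf bundle/catalog.vcf --out qc/
rviskit run-all --config pipeline.yaml     # all stages + SHA-256 manifest
```

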