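# Methods

## The constraint model

RVIS treats a gene's common functional variation as predictable from
its total mutational burden. With `X_g` the count of protein-coding
variants in gene *g* (missense + LoF + synonymous, after quality
screening) and `Y_g` the count of *common functional* variants
(missense/LoF at allele frequency ≥ the MAF threshold), ordinary least
squares of `Y` on `X` with intercept is fit across all genes, including
genes with zero counts — every annotated autosomal gene participates,
so genes invisible in the catalog score near the regression line rather
than being silently dropped. The score is the studentized residual:

* **external** (default): residual divided by `s₍₋g₎·√(1−h_g)`, where
  `s₍₋g₎` is the residual standard error of the fit with gene *g*
  removed and `h_g` its leverage. This is the leave-one-out form; an
  `internal` flavor (single global `s`) is available for sensitivity
  checks and differs negligibly at genome scale.
* Scores are then re-centered to mean exactly 0 over the fitted genes.
  Raw externally studentized residuals have only approximately zero
  mean; the centering (a constant shift of order 1/√n) makes "RVIS = 0
  means average behavior" exact and matches how the score is described
  and plotted. The uncentered residual is kept in the output table.

**Degenerate cases.** If the global fit is exact (zero residual
variance) all scores are 0 and the table is flagged. If a single
leave-one-out fit is exact — possible at small n when the remaining
points are collinear — that gene's score is ±infinity (it is infinitely
surprising under a perfect model of the others); infinities survive to
the output, are ignored by the centering, and are caught by the outlier
screen. Ties in `(X, Y)` give identical scores; output order is
canonical (sorted by gene label) regardless of input order.

**Outlier removal** is one-sided: genes scoring above +11 (hyper-
variable outliers, e.g. mucin genes) are excluded and the regression
and studentization recomputed once on the remainder. Strongly negative
(constrained) genes are never removed, and the refit scores are not
re-screened — a single pass, then analysis.

**Key parameters.**

| parameter | default | meaning |
|---|---|---|
| `maf_threshold` | 0.001 | common/rare split for Y (fraction, i.e. 0.1%) |
| `outlier_threshold` | 11 | one-sided exclusion cutoff on the score |
| `residual_flavor` | external | leave-one-out vs global variance estimate |

The MAF threshold follows the original human RVIS convention; it is
exposed because catalogs of different cohort sizes resolve different
frequency floors.

## Quality screen

Variants are kept iff QUAL ≥ 30, site depth within [10, 50], single-
nucleotide substitution, and autosomal (default labels chr1–chr20, the
rhesus autosomes). Published bounds are strict exclusions ("< 30",
"< 10 or > 50"), so the boundary values 30, 10 and 50 are retained.
Each dropped record is attributed to exactly one reason with fixed
precedence qual → depth → indel → non-autosome, making the counts
conserve (`input = retained + Σ dropped`) under any input order.
Multi-allelic sites are split per ALT allele before filtering so that
per-allele effect annotations stay attached to the right allele.
Depth is the site-level INFO `DP`; per-sample depth aggregation is out
of scope because population catalogs distribute site-level records.

## Gene-set statistics

* **Welch t-test**, two-sided, with Welch–Satterthwaite degrees of
  freedom: group sizes are very unbalanced (hundreds vs ~18k), where
  the unequal-variance correction matters. Background = all scored
  genes not in the set, after outlier exclusion.
* **Logistic regression** of membership on RVIS, `OR = exp(β)` per
  1-unit score increase, Wald SE and p. Complete separation is detected
  directly (disjoint score ranges of the two classes) and raised as an
  error, since the MLE does not exist there.
* **Cross-species correlation**: Pearson r over the inner gene join of
  two score tables, Fisher-z 95% CI; for n ≤ 3 the CI is vacuous
  (−1, 1). Symbol matching is case-sensitive exact by default, with an
  optional uppercasing hook.

## Enrichment over the constraint ranking

Genes are ranked ascending (most constrained first); ties break by gene
label so the ranking is deterministic. The enrichment score is the
signed extremum of the unweighted KS running sum (hit +1/Nh, miss
−1/(N−Nh)), positive when set members cluster toward the constrained
top. The permutation null redraws random member sets of the same size
from the ranked genome — equivalent to permuting gene labels and
cheaper than re-ranking — and the p-value carries a +1 correction,
`p = (1+exceed)/(n_perm+1)`, so it can never be 0. Exceedance is
two-sided on |ES|.

The over-representation test is the upper-tail hypergeometric
probability of the observed set count among the top `floor(N×fraction)`
genes (default fraction 0.02). Note `floor(18,166 × 0.02) = 363`; a
truncation-vs-rounding ambiguity can also produce 369 for the same
universe, and this package uses the floor convention throughout. Set
members absent from the ranked universe are dropped from K with a
warning.

## Liftover and overlap

UCSC chain files are parsed with full block/gap bookkeeping; the
declared interval ends must match the cumulative arithmetic or parsing
fails naming the chain id. Point positions inside an aligned block map
by offset, with coordinate reflection for negative destination strands;
positions in gaps or outside all chains are *unmapped*, never errors.
When several chains cover a position the highest-scoring chain wins
(the UCSC convention). No installed library parses chain files, so this
component is implemented here and validated by round-trip identity
through algebraically inverted chains.

A disease-catalog match requires the lifted (chrom, pos) *and* the
exact ref/alt alleles; a strand-aware allele flip (reverse complement
on '−' strand) is available behind a flag but off by default — silent
allele reconciliation can fabricate matches. The damaging designation
(ClinVar-pathogenic / PolyPhen2 / SnpEff-high flags) and CADD scores
are consumed from input annotations, never computed. Per-set damage
proportions are gene-level presence (≥ 1 damaging variant), so
duplicating variants cannot change them; percentages round half-up to
one decimal.

## Synthetic catalogs

The generator emulates the statistical skeleton of a population variant
catalog, with all randomness from one `numpy` Generator seeded by the
config, making the bundle byte-identical across runs:

* **Per-gene burden** `X ~ NegBin(mean 40, dispersion 5)` — genes'
  variant counts are overdispersed relative to Poisson (Poisson is the
  large-dispersion limit, so one knob covers both).
* **Constraint**: a fraction (default 0.25) of genes is constrained;
  `Y ~ Binomial(X, p₀·c)` with baseline common-functional rate
  `p₀ = 0.4` and constraint factor `c = 0.3` (unconstrained genes use
  `c = 1`). `Y ≤ X` by construction.
* **Alleles and effects**: common functional variants draw AF uniform
  in [MAF, 0.5]; the remaining coding variants are synonymous (any AF)
  or rare functional (AF below the MAF threshold); a small Poisson
  count of noncoding variants per gene exercises the coding filter.
  Effects come from a controlled vocabulary (missense, lof, synonymous,
  noncoding) in the VCF INFO, avoiding any annotation-tool dependency.
* **Gene sets**: four NDD-like sets sized at the genome fractions of
  curated disease lists (ASD 4.4%, ID 8.6%, epilepsy 4.8%,
  schizophrenia 11.1% of genes), each drawing 80% of members from the
  constrained pool. This bias level was fixed by a power analysis: it
  makes every downstream statistic (mean-score gap, logistic slope,
  enrichment score, top-tail over-representation at p < 0.01) detect
  the signal in ≥95% of 2,000-gene replicates, which is the
  detectability regime the package's recovery tests certify.
* **QC noise**: configurable fractions of extra variants violating
  exactly one screen rule each (binomially drawn counts, recorded in
  the bundle metadata), so filter attribution can be checked exactly.
* **Toy assemblies**: one chain block per autosome with a constant
  signed offset; the disease catalog contains a configured number of
  entries exactly matching lifted damaging variants, plus decoys
  guaranteed not to match.

**What the generator does not emulate** — linkage disequilibrium,
pedigree/admixture structure, sequencing-platform error profiles, a
realistic allele-frequency spectrum, or gene-length/GC covariation with
burden. Passing recovery tests therefore show the *pipeline* is correct
and well-calibrated under its model assumptions, not that the model
captures every property of real cohort data.

## Null calibration

With `constraint_factor = 1` constrained and unconstrained genes are
exchangeable, so set membership carries no signal. The test suite
checks that Welch and logistic Wald p-values are then uniform
(Kolmogorov–Smirnov, α = 0.01, 200 replicates). Permutation and
hypergeometric p-values are discrete and conservative by construction —
exact uniformity is mathematically false for them — so they are checked
for super-uniformity instead (fraction below 0.05 not exceeding 0.05
plus 3 binomial SE).

## Problem sizes

Tests and the acceptance script run on 2,000-gene catalogs (the scale
at which all statistics are comfortably powered), 100-replicate
recovery suites, 200-replicate null suites and 2,000-permutation
enrichment nulls; small-instance oracle comparisons (leave-one-out OLS
refits at n ≤ 50, KS running-sum enumeration at N ≤ 30, hypergeometric
enumeration at N ≤ 20) pin the numerics exactly. These sizes are the
package's chosen verification scale; every operation accepts
genome-scale inputs.

## Pipeline

`run-all` executes simulate → qc → rvis → stats → gsea → overlap from
one YAML config. Per-stage seeds derive from the global seed by hashing
the stage name (adding a stage never shifts another stage's stream),
and every artifact is recorded in a JSON manifest with its SHA-256,
so a rerun with the same config proves itself identical. Subcommands
are thin wrappers over the same stage functions, so manual stage-by-
stage runs produce byte-identical outputs.

## Known limitations

* SNV-only: indels are screened out upstream and the liftover maps
  single positions, not intervals.
* The logistic model is univariate; gene length or GC covariates are
  out of scope.
* Chain inversion (for round-trip checks) supports '+'/'+' chains only.
* The score's behavior under very sparse catalogs (most genes X = 0)
  degrades gracefully but has not been a design target.
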