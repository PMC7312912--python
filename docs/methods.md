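# Methods

## Scope and data model

The package analyzes gene × sample expression matrices from a 2×2 factorial
study: two genotypes (`wt`, `ko`) crossed with two treatment levels
(`untreated`, `treated`). Matrices carry an explicit scale tag — `count`
(integer-valued raw counts), `fpkm`, or `normlog` (natural-log of normalized
FPKM) — and stages refuse input on the wrong scale rather than guessing.
Sample exclusion is declarative: an `include` flag in the design table, not
automatic read-quality control, which keeps a matrix-level pipeline
deterministic (upstream read QC is out of scope). Gene identifiers are
matched as exact strings; mapping between namespaces (symbol vs Ensembl,
cross-species) is the caller's job.

## Synthetic data generator

`synthetic.generate` draws counts from a negative binomial in the mean/size
parameterization: a gene with mean μ and size (dispersion) φ has variance
μ + μ²/φ. Per gene and sample,

    log2 μ = log2(baseline) + (e_g/2)·G + (e_t/2)·T + (e_gt/2)·G·T + log2(libfactor)

with G, T the ±1 cell codes. Planting effects on the same coding the
factorial model fits gives closed-form recovery targets: a planted log2
genotype effect e_g is exactly the expected ko-vs-wt log2 fold change, and
the factorial coefficient `beta_g` estimates e_g·ln2/2 on the natural-log
scale.

Defaults, chosen once as a realistic desk-scale bulk RNA-seq emulation:

| parameter | default | meaning |
|---|---|---|
| `baseline_mean` | 200 | expected count of a null gene in an average library |
| `dispersion` | 10 | NB size; moderate biological noise (CV ≈ 0.33 at the baseline) |
| `n_per_cell` | 4 | replicates per design cell (group sizes at the small end of bulk studies) |
| `libsize_factors` | lognormal(0, 0.15) | modest sequencing-depth variation |
| `gene_lengths_bp` | uniform 500–5000 | transcript lengths for the FPKM formula |
| `frac_mito` | 0.1 | fraction labeled mitochondrial (≈ a MitoCarta-sized set relative to an expressed transcriptome, at reduced scale) |

Recovery and validation scenarios use `dispersion=50` ("low noise": CV ≈
0.15) with |log2| = 2 planted effects — strong, cleanly detectable signals.
The optional low-quality sample has its library factor forced to 0.05 and
`include=False`, to exercise the exclusion path.

What the generator does *not* emulate: gene–gene correlation, batch
effects, GC/length biases beyond the FPKM formula, count outliers, or
read-level artifacts. Tests passing on this generator therefore demonstrate
the pipeline's statistical logic and numerics, not robustness to every
failure mode of real libraries.

FPKM conversion is the standard `count × 10⁹ / (length_bp × libsize)` with
library size defaulting to the column sum.

## Normalization chain

Order of operations: **quantile normalize → filter → floor → ln**.

* Quantile normalization replaces each sample's k-th order statistic with
  the mean of k-th order statistics across samples. Ties within a sample
  receive the mean of the target values their ranks span — deterministic and
  rank-preserving. Note a consequence: a tie-group average is not itself a
  target order statistic, so when ties are present the columns' sorted
  multisets agree only up to tie aggregation (the property tests assert
  exact agreement for tie-free columns).
* The expression filter keeps genes whose maximum is **strictly** greater
  than 3 FPKM in at least one sample, decided on the FPKM scale before the
  log transform.
* The floor (default 5) is applied to normalized values before the natural
  log, preventing noise-dominated near-zero values from exploding on the
  log scale. Whether flooring should precede quantile normalization is
  genuinely open; we fix normalize-then-floor and expose both parameters.

## Two-group differential expression

A per-gene Welch (unequal-variance) t test on `normlog` values;
log2 fold change = (mean_B − mean_A)/ln 2; BH adjustment across genes. This
is a deliberate, clearly labeled stand-in for a count-model DE engine
(dispersion shrinkage, independent filtering and outlier handling are
non-goals); the gating/overlap logic accepts external DE tables so a
negative-binomial engine's output can be used instead. Gates are strict:
|fold change| > 2 **and** p < 0.01, on the raw p-value by default (the
adjusted value is always reported; `use_adjusted=True` switches the gate).
Degenerate genes with zero variance in both groups get p = 1 when the means
agree (no evidence) and p = 0 in the distinct-constants limit.

## Factorial model

For two-level factors the finite orthogonal (Chebyshev) polynomial system
reduces to the ±1 linear contrast, so the design matrix is
`[1, G, T, G·T]`; in a balanced design the columns are orthogonal and the
model is the classical orthogonally coded two-way ANOVA (the tests verify
t² = F against an independent ANOVA fit). Unbalanced designs — e.g. after
dropping a low-quality sample — are handled by plain OLS on the same
columns, which remain full rank; no rebalancing.

Inference: per-coefficient t tests with n − 4 residual degrees of freedom;
BH adjustment applied across genes separately within each effect family
(genotype, treatment, interaction), because the selection threshold is
stated per main effect. "Dual significant" = adjusted p < 0.01 for **both
main effects**; the interaction family is reported but not used for
selection unless `include_interaction=True` — the alternative reading of
"affected by both factors". Coefficients are estimated for any full-rank
design with n ≥ 4; with zero residual degrees of freedom the t/p columns
are NaN (estimation is defined, inference is not).

## Multirun random-forest selection

"Most frequently chosen for the prediction model" is operationalized as
membership in the per-iteration top-k by impurity (Gini) importance:

1. For iteration i = 1…n_iter, fit a RandomForestClassifier with `n_trees`
   trees on samples × genes (RNG stream spawned from the master seed by
   iteration index, so runs parallelize without changing results).
2. Rank genes by decreasing importance, ties broken by gene order.
3. Record membership in the top `k_top` (default 50).
4. `selection_frequency` = membership count / n_iter;
   the final list is the frequency-ranked top `n_select` (default 50), ties
   broken by mean importance rank, then gene ID.

Defaults are 1000 trees × 1000 iterations; the tests and the acceptance
script run 100 × 100, which preserves the selected set on strongly separable
data (asserted by a reduced-scale equivalence test). The 50-gene list size
is treated as a preset (`n_select`), not a frequency threshold; both `k_top`
and `n_select` are exposed.

## PCA / LDA validation

PCA operates on the gene-restricted, per-gene mean-centered matrix;
components are ordered by decreasing variance with a fixed sign convention
(largest-magnitude loading positive) so scores are reproducible. LDA
accuracy is reported two ways: leave-one-out cross-validation (the primary,
honest small-n figure) and resubstitution (the optimistic in-sample figure,
for comparison with analyses that do not state their validation scheme).
Because the gene list typically exceeds the sample count, each training
fold is projected onto its leading `min(n_train − 2, n_genes)` principal
components before fitting LDA — a parameter-free alternative to covariance
shrinkage.

## Gene-set enrichment and heatmap ordering

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) for overlap k between the hit list and each set, BH-adjusted
across sets, flagged enriched at FDR < 0.05. This replaces web-service
annotation tooling with the standard reproducible offline test. The default
background universe is the post-filter expressed genes (not the whole
annotation), the usual guard against expression-filter bias; when a GMT
collection is read against such a universe, set members outside it are
dropped.

Heatmap ordering clusters genes by complete linkage under
d(i, j) = 1 − Pearson r across samples (zero-variance genes are rejected by
name), returns the dendrogram leaf order, and mean-centers each gene row so
a diverging color scale splits at the gene's mean.

## Numerical conventions and problem sizes

* All threshold comparisons in gates and selections are strict (>, <).
* BH adjustment is the step-up procedure, clipped at 1 (verified against a
  hand-rolled independent implementation and printed toy vectors).
* OLS uses the normal-equations solution via a single inverse of X'X shared
  across genes; agreement with a direct solve is asserted to 1e-10.
* RNG: `numpy.random.Generator` seeded from explicit integers everywhere;
  forest iterations use `SeedSequence.spawn` children.
* Test and acceptance problem sizes — 1000 genes, 5 samples per class,
  100 × 100 forests, 20-seed null calibration, 250-replicate uniformity
  checks — were chosen as the smallest scales at which the statistical
  claims are cleanly decidable.
* The null-calibration Monte-Carlo for the Welch test applies floor+log
  without quantile normalization: QN across a 5-gene replicate would
  distort marginals at that width, and the claim under test is the test's
  calibration, not QN. Full-pipeline null behavior is covered by the
  1000-gene dual-significance check.

## Known limitations

* The Welch stand-in loses power relative to NB count models at very low
  counts; use an external DE table when that regime matters.
* Impurity importance is biased toward high-cardinality/high-variance
  features; with all features on a common normalized log scale the bias is
  mild, but permutation importance is deliberately out of scope.
* Hypergeometric enrichment treats genes as exchangeable; correlated gene
  sets (co-expression) inflate significance, as with any ORA.
* LDA validation assumes two classes; multi-class designs are out of scope.
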