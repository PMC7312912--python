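# mitofactor

A tested, reusable pipeline for transcriptome studies with a 2×2
genotype × treatment design, built around the question of how loss of a gene
(e.g. a *Ube3a* knockout in mouse embryonic fibroblasts) changes the
expression of mitochondria-associated genes, at rest and under a
mitochondria-stressing stimulus such as TNFα.

It is aimed at bioinformaticians who have a gene × sample expression table
(FPKM or raw counts plus gene lengths), a sample design table, and gene-set
collections (e.g. a MitoCarta-style mitochondrial localization set), and who
want the full analysis chain offline and reproducible:

1. **Normalization** — quantile normalization across samples, a floor at 5
   followed by a natural-log transform, and a filter keeping genes above
   3 FPKM in at least one sample.
2. **Two-group differential expression** — per-gene Welch t tests on
   normalized log expression with strict |fold change| > 2, p < 0.01 gates,
   Venn overlap accounting and direction-of-change summaries. (A stand-in
   for a count-model DE engine; externally computed DE tables can be slotted
   in via `de --external-de`.)
3. **Factorial modeling** — per-gene OLS of
   `y = b0 + b_g·G + b_t·T + b_gt·G·T` with orthogonal ±1 contrasts
   (the two-level orthogonal-polynomial coding), per-effect t tests,
   Benjamini–Hochberg adjustment per effect family, and selection of genes
   with BH-adjusted p < 0.01 for **both** main effects.
4. **Multirun random-forest selection** — repeated 1000-tree forests (1000
   iterations by default), per-iteration importance top-k membership,
   cross-iteration selection frequencies, and a fixed-size (default 50-gene)
   classifier list.
5. **Validation** — unsupervised PCA separation and supervised two-class LDA
   with leave-one-out cross-validation (PCA pre-projection per fold keeps
   the within-class covariance well conditioned when genes ≫ samples).
6. **Gene-set work** — intersection with expressed genes, hypergeometric
   over-representation with BH/FDR gating (an offline replacement for
   web-service annotation tools), and heatmap-ready complete-linkage
   clustering under the Pearson distance with per-gene mean centering.

A negative-binomial simulator (`mitofactor.synthetic`) generates count
matrices for the 2×2 design with planted genotype/treatment/interaction
effects, a labeled mitochondrial gene subset, library-size variation and an
optional low-quality sample, so every stage has a ground-truth recovery test.

## Worked example

```python
import mitofactor as mf

# simulate a 2x2 study: 30 genes carry both a genotype and a treatment
# effect of |log2| = 2; low biological noise (NB size 50)
effects = {i: (2.0 if i % 3 else -2.0) for i in range(30)}
cfg = mf.SimulationConfig(
    n_genes=500, n_per_cell=4, baseline_mean=200.0, dispersion=50.0,
    genotype_effects=effects, treatment_effects=effects, seed=7,
)
counts, design, truth = mf.generate(cfg)
fpkm = mf.counts_to_fpkm(counts, truth.set_index("gene_id")["length_bp"])
norm = mf.normalize_pipeline(fpkm, floor=5.0, min_fpkm=3.0)

res = mf.fit_factorial(norm, mf.encode_design(design))
dual = mf.select_dual_significant(res, alpha=0.01)

labels = design.set_index("sample_id")["genotype"]
sel = mf.multirun_rf(norm, labels, n_trees=100, n_iter=100,
                     k_top=30, n_select=30, seed=1)
top = sel.loc[sel["selected"], "gene_id"]
acc = mf.lda_loo_accuracy(norm, top, labels)
```

This prints (via the obvious `print` statements):

```
500 genes x 16 samples after normalization
30 dual-significant genes (BH adj p < 0.01 for both main effects)
30 of 30 planted genes recovered
RF classifier list: 30 genes; LOO-LDA accuracy 1.00
```

All 30 genes planted with both main effects are recovered by the factorial
dual-significance screen with no false positives among the 470 null genes,
and the stability-selected classifier genes separate the genotypes perfectly
under leave-one-out LDA. An enrichment call against a random "mito" set
shows, as it should, no over-representation (p ≈ 0.96).

The same pipeline is available from the shell:

```bash
mitofactor simulate --n-genes 500 --seed 7 --out-dir run/
mitofactor normalize --matrix run/fpkm.tsv --design run/design.tsv --out run/norm.tsv
mitofactor factorial --matrix run/norm.tsv --design run/design.tsv --out run/factorial.tsv
mitofactor select --matrix run/norm.tsv --design run/design.tsv --seed 1 --out run/rf.tsv
```

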