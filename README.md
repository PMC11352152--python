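# budnet

Biomarker discovery for small, imbalanced RNA count cohorts by combining a
negative-binomial differential-expression test, mutual-information screening,
and regularized-Laplacian diffusion over a protein–protein interaction (PPI)
network, with local hypergeometric pathway enrichment of the diffusion
neighborhood.

The motivating setting is tumor-budding (TB) transcriptomics in breast
cancer: a cohort of 15 formalin-fixed tissue samples profiled with a
targeted counting assay, split 12 high-TB vs 3 low-TB by the ITBCC bud-count
categories (low 0–4, intermediate 5–9, high ≥10 buds per high-power field).
With three samples in one arm, a mean-comparison test alone is fragile; the
pipeline therefore intersects two orthogonal screens before any network
analysis, and ships a synthetic-data generator that reproduces the design so
every stage is testable without any download.

## Method

1. **Preprocess** — probe-level counts are collapsed to genes by keeping the
   probe with the maximal mean count (selection, not summation), then
   depth-normalized with median-of-ratios size factors
   `s_j = median_g (c_gj / (prod_k c_gk)^(1/n))`.
2. **Differential expression** — per-gene NB dispersion by method of moments
   (`var = mu + alpha*mu^2`), a two-group NB GLM with log link fitted by
   IRLS at fixed dispersion, Wald statistic `stat = logFC / lfcSE` with
   `logFC = log2(x_high / x_low)`, two-sided normal p-values,
   Benjamini–Hochberg adjustment, and the DEG filter
   `padj < 0.05 AND |logFC| > 1.5` (strict). This is a deliberately
   simplified reimplementation of the DESeq2-style workflow — no Cox–Reid
   dispersion shrinkage, outlier replacement, or independent filtering.
3. **Mutual information** — `MI(X,Y) = H(X) + H(Y) − H(X,Y)` in nats between
   each gene's discretized normalized expression X and the binary class Y.
   With 12 vs 3 samples the ceiling is the class entropy
   `H(Y) = −(0.8 ln 0.8 + 0.2 ln 0.2) = 0.5004`, attained exactly by genes
   that perfectly separate the classes; the default selection keeps the
   full tie set at the maximum.
4. **Seeds and diffusion** — the DEG ∩ MI intersection seeds a diffusion
   over the weighted PPI graph (STRING-style edges, combined score > 0.4):
   with Laplacian `L = D − W`, scores solve `(I + αL) s = y` for the binary
   seed indicator y (the regularized Laplacian kernel `K = (I + αL)^{-1}`
   applied to y, computed by sparse conjugate gradient, never a dense
   inverse). The top `ceil((1 − q/100)·n)` non-seed nodes at percentile q
   (default 99) become candidates — 191 nodes on a 19,038-node network.
5. **Enrichment** — upper-tail hypergeometric over-representation of the
   candidates + seeds against a GMT collection within an explicit universe
   (network nodes), set sizes 10–500, p < 0.01, BH-corrected, sorted by
   gene ratio k/K.
6. **Evaluation** — sample–sample Pearson correlation, top-2 PCA, and a
   silhouette separation score of the classes on any gene panel
   (log2(x+1) scale).

## Worked example

Run the default synthetic study (2000 genes, 12 vs 3 samples, 5% planted DE
genes at |log2FC| ≈ 2.5, 7 planted perfect separators, a 500-node scale-free
PPI network, 50 gene sets of which 3 are planted around the seeds):

```bash
budnet run --outdir demo_run --seed 7
```

prints

```
candidates: 5; enriched sets: 3; separation: 0.8174
```

and writes all intermediate tables to `demo_run/`. In that run the DE stage
finds 99 DEGs, 87 genes tie at the MI ceiling 0.5004, their intersection
gives 81 seed genes (25 of which lie in the network), the 99th percentile of
the diffusion scores adds 5 candidate nodes, and all three planted pathways
are recovered — the top one with gene ratio 0.64:

```
set_name  overlap_k  set_size_K  query_n  universe_N  pvalue        padj         gene_ratio
PW0002    7          11          30       500         3.83e-07      1.91e-05     0.636
PW0001    10         34          30       500         6.36e-06      1.59e-04     0.294
PW0000    9          41          30       500         2.77e-04      4.62e-03     0.220
```

The separation score 0.82 is the mean silhouette of the low/high classes on
the seed panel: the intersection panel cleanly clusters the two classes,
which is the quantitative analog of the correlation-heatmap/PCA evidence the
approach is built on.

Every stage is also available separately (`budnet simulate`, `preprocess`,
`diffexp`, `mi`, `diffuse`, `enrich`, `evaluate`), reading and writing plain
TSV/GMT files.

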