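# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that make runs reproducible.

## Study design assumptions

The pipeline targets a two-class contrast on a gene × sample integer count
matrix with a small, imbalanced design (reference design: 12 high- vs 3
low-tumor-budding samples; intermediate samples carry no class label and are
excluded from the contrast). Counts are assumed negative-binomial with
per-sample depth (size) factors; identifiers are plain gene symbols
throughout, and the PPI edge list is assumed to be pre-mapped to the same
symbol space (no protein-to-gene identifier mapping is attempted).

## Preprocessing

**Probe collapse.** When several probes measure one gene, the probe row with
the maximal raw mean count is kept verbatim. Selection rather than summation
preserves the per-probe count distribution; the mean is computed on raw
counts because collapse precedes normalization in the workflow. Ties are
broken by lexicographically smallest probe id so the collapse is
deterministic.

**Size factors.** Median-of-ratios: `s_j = median_g(c_gj / g_g)` with `g_g`
the geometric mean of gene g across samples, restricted to genes positive in
every sample. Size factors are defined only up to a global constant; the
tests therefore assert ratio-level equivariance (scaling one sample's depth
by 10 multiplies its *relative* factor by exactly 10) rather than absolute
values, matching how the method is used — normalized counts are compared
across samples, not across datasets.

**Bud categories.** ITBCC: 0–4 low, 5–9 intermediate, ≥10 high, per
high-power field.

## Differential expression

A documented, simplified NB Wald workflow:

- **Dispersion** (`var = mu + alpha*mu^2` parameterization): per-gene method
  of moments on the normalized scale, pooled across classes with df weights,
  `alpha_hat = max(0, sum_c (n_c−1)(v_c − m_c) / sum_c (n_c−1) m_c^2)`,
  floored at 1e-8 when used in the fit. An optional `trend` mode replaces
  the gene-wise value with a mean-dispersion trend `a/mu + b` fitted by
  least squares — the smallest useful form of shrinkage for very small n.
  With one class of size < 2 the estimator falls back to the other class
  with a warning (the reference design has 3 in the low arm, so both
  classes contribute).
- **Fit**: two-group NB GLM with log link and offset `log s_j`, IRLS with
  expected-information weights `mu/(1 + alpha*mu)`, vectorized across genes
  (the 2×2 normal equations solve in closed form). At `alpha = 0` this is
  exactly the Poisson GLM, which the tests verify against statsmodels to
  1e-6.
- **Wald test**: `logFC = b1/ln 2`, `lfcSE` from the observed information,
  `stat = logFC/lfcSE`, two-sided standard-normal p. No logFC shrinkage is
  applied (effect estimates are unshrunken MLEs).
- **Degenerate genes**: a gene with all-zero counts in one class has no
  finite MLE; its zero class mean is replaced by the pseudo-mean
  `0.5 / mean(s_j)` and the row is flagged (`zero_class`). All-zero genes
  are excluded from testing and do not count toward the BH denominator.
- **DEG filter**: `padj < 0.05` and `|logFC| > 1.5`, both strict.

Known behavior at n = 12 vs 3: the Wald test is mildly anti-conservative
(raw type-I fraction at 0.05 sits around 0.06–0.09 in null simulations); the
BH step and the fold-change filter keep the realized false-discovery rate of
the DEG list near zero in the planted-truth simulations. Bit-compatibility
with DESeq2 is out of scope by design: no Cox–Reid MAP dispersion, no Cook's
outlier handling, no independent filtering.

## Mutual information

`MI = H(X) + H(Y) − H(X,Y)` in natural-log units on discretized normalized
expression. Discretization is a config knob (the log base is pinned by the
0.5004 = H(12/15, 3/15) ceiling, but no particular binning is canonical):

- `equal_width` (default): uniform edges over [min, max];
- `equal_frequency`: interior quantile edges with duplicates collapsed, so
  the category count never exceeds the requested bins;
- `distinct`: one category per unique value.

Default bin count is Sturges-like, `min(ceil(log2 n) + 1, #distinct)`. A
gene whose discretized categories align perfectly with the class attains
`H(Y)` exactly; selection keeps either the full tie set at the maximum
(`max_ties`, tolerance 1e-9, the default) or a boundary-tie-inclusive top-k.
MI is clipped at 0 to absorb floating-point negatives.

## Network diffusion

Graph: undirected, weighted by STRING-style combined scores in (0, 1]
(edges kept strictly above 0.4 on read; the published 0–999 integer scale is
auto-detected and divided by 1000). Seeds are the DEG ∩ MI intersection;
seeds absent from the network are reported and excluded from the indicator.

Scores solve `(I + αL) s = y`, `L = D − W`. The system is symmetric positive
definite; a diagonally preconditioned conjugate gradient (rtol 1e-10) solves
it without materializing the kernel. Two structural facts are asserted in
tests: `sum(s) = sum(y)` (L has zero row sums, so the kernel preserves total
seed mass) and `s ≥ 0` (`I + αL` is an M-matrix). Components with no seed
receive exactly zero. `α` defaults to 1.0 and is exposed — no canonical
value exists for this kernel, and the CLI help says so; larger α flattens
the score field toward uniformity (variance decreases monotonically in α on
connected graphs).

**Percentile rule.** Candidates are the top `ceil((100 − q)·n/100)` non-seed
nodes by score (ties broken by node id), with n the total node count. This
rank-quota reading is the one consistent with a 19,038-node network at
q = 99 yielding 191 candidates; a seed-inclusive mode is available. The
quota arithmetic uses `(100 − q)·n/100` to avoid float noise at exact
boundaries.

## Enrichment

Upper-tail hypergeometric p-value `P(X ≥ k)` for overlap k between the query
and a gene set of effective size K (after intersection with the declared
universe), query size n, universe size N — summed exactly in log space. The
universe is explicit (network nodes when enriching diffusion output; all
measured genes when enriching a DEG list) because web-service universes are
not reproducible. Sets are tested only at effective size 10–500; rows with
p < 0.01 (strict) are kept, BH-adjusted across all tested sets, and sorted
by gene ratio k/K descending.

## Panel evaluation

Correlation, PCA and the separation score all operate on `log2(x + 1)`
normalized expression restricted to the panel; the pseudocount-1 log is a
documented default (the transform used by the reference figures is not
specified anywhere authoritative). PCA standardizes genes and fixes each
component's sign by its largest-magnitude loading, so repeated runs are
identical. The separation score is the mean silhouette of the two classes
(Euclidean); a singleton class contributes the conventional silhouette of 0
for its sample and triggers a warning. Silhouette was chosen because it
turns the usual visual clustering argument into a single number in [−1, 1].

## Synthetic data

`simulate_counts` draws `c_gj ~ NB(s_j·q_gc, alpha)` with log-uniform size
factors over (0.5, 2.0) and lognormal baseline means (median 100, log-sd
1.2). A fraction (default 5%) of genes receives a symmetric log2 effect of
random sign drawn around 2.5 (sd 0.25), split evenly between the classes so
the base mean is preserved. Default dispersion is 0.1, shared across genes
(optional gamma-distributed per-gene dispersions exercise the estimator).

Seven planted separators (a subset of the DE genes, mirroring the reference
seed-set size) are exactly zero in one class and tightly clustered
Poisson values (mean ≥ 500, floored at 1) in the other: their value ranges
cannot overlap after normalization, so they attain the MI ceiling `H(Y)`
under every discretization method — this is what pins the MI stage's
worked value of 0.5004 at 12 vs 3.

`simulate_network` produces a Barabási–Albert graph (default m = 3; edge
count exactly m(n−m)) with weights uniform in (0.4, 1.0], or a
stochastic-block graph for community-locality tests. `simulate_pathways`
plants `n_enriched` sets that contain the seed genes themselves plus
members drawn from the seeds' 1-hop (preferred) and 2-hop neighborhoods
(≥ 70% of members within 2 hops); the remaining sets are uniform draws. The
pipeline's synthetic defaults use 50 sets of size 10–50 on a 500-node
network — a set-to-universe ratio at which over-representation is a
meaningful question at desk scale.

**What the generator does not emulate:** probe-level chemistry or
attenuation, FFPE degradation, correlated gene–gene expression modules,
library-size distributions of any particular assay, or degree-weighted
placement of true biology on the network. Passing tests demonstrate that
the pipeline recovers structure it is designed to detect under its own
model assumptions — not that those assumptions hold for any particular
real dataset.

## Determinism and numerical conventions

Every stochastic routine takes one integer seed; the pipeline derives stage
seeds by fixed offsets from it and keeps no global RNG state, so a config +
seed pair reproduces byte-identical artifacts. Node and gene orderings are
sorted before any solve or selection; score ties break by identifier.
Floats are written with 12 significant digits (round-trips within 1e-9).
Problem sizes used by the test suite (2000-gene cohorts, 20 replicates for
the recovery and null checks, 500-node networks end to end) were chosen so
the full suite documents the statistical claims while remaining quick to
run on one CPU.

## Known limitations

- The Wald test is anti-conservative at n = 3 per arm; the pipeline relies
  on the intersection with the MI screen rather than the test alone.
- Method-of-moments dispersion is noisy at these sample sizes; the trend
  mode trades bias for variance but neither matches a full MAP estimator.
- The MI ceiling argument pins only the log base and the existence of
  perfect separators, not any particular binning of real expression data.
- Enrichment results depend strongly on the declared universe; counts of
  significant pathways are not comparable across universes or gene-set
  collections.
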