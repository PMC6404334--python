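# Methods

## Model and procedure

`gsepd` analyses a two-group contrast on a raw RNA-seq count matrix in five
stages. Samples belonging to neither contrast group ("non-tested") are kept
throughout: they contribute to clustering and receive projection scores, but
carry no class label and therefore never enter the V-measure or the
permutation null.

**Normalization.** Size factors are median-of-ratios: for sample j,
s_j = median over reference genes i of c_ij / geomean_i, where the reference
is the set of genes with positive counts in every sample (a zero count makes
the geometric mean zero and the ratio degenerate). The median is taken on
the ratio scale. Expression used everywhere downstream is
x_ij = log2(c_ij / s_j + pseudocount), pseudocount 1 by default so a zero
count maps to 0. Size factors are defined only up to a common scale; the
invariant that survives rescaling is that multiplying one column by c
multiplies that sample's factor by c *relative to every other sample*.

**Differential expression.** The internal test is Welch's unequal-variance
t-test per gene on x, two-sided, with BH adjustment across all tested genes.
log2 fold-change is mean(group B) − mean(group A), so positive means higher
in B. Genes constant across both groups get p = 1. This simple test is a
deliberate design choice: count-model machinery (negative-binomial GLMs,
dispersion shrinkage, outlier handling) is out of scope, and studies wanting
it run DESeq2 or similar externally and load the result table
(`load_de_table` auto-recognizes DESeq2 column names; rows with NA p-values
are kept but never called DE). DE calls default to raw p < 0.05 — the gate
the downstream stages key on — with padj reported and selectable.

**Over-representation.** For each gene set and each of the up/down/all DE
lists, the upper-tail hypergeometric probability of the observed overlap,
within the universe of genes that have a defined DE p-value (the genes
actually tested, not all annotated genes). Set membership is intersected
with the count matrix's genes once, up front; that intersected size is the
set size used everywhere, including the m-filter. BH runs separately within
each direction. The gate for the clustering stage is the 'all'-direction raw
p < 0.05 (configurable to padj or another direction). Gene length bias is
not modeled: the test is the plain hypergeometric, with a per-gene-weight
hook reserved on the interface for a future biased-urn mode.

**Clustering and validity.** Each candidate set with
min_set_size ≤ size < m (defaults 2 and 31; "less than m" is strict) defines
a subspace with one dimension per member gene. All samples are clustered by
2-means with Euclidean distance. Concordance between clusters and class
labels, restricted to tested samples, is the V-measure: with contingency
counts n_ck, h = 1 − H(C|K)/H(C) (defined as 1 when H(C) = 0),
c = 1 − H(K|C)/H(K), v = 2hc/(h+c) (0 when h = c = 0), using 0·log 0 = 0.
The value is independent of the entropy base.

**Permutation p-value.** Clusters do not depend on class labels, so the
clustering is computed once and only the V-measure is recomputed per
permutation. When the number of distinct label assignments C(n, n_A) is
within the permutation budget B (default 400), every assignment is scored:
p is the exact proportion with v ≥ v_observed, which includes the identity
assignment and so is never zero (a 3v3 design bottoms out at 2/20, the true
labeling and its mirror). Otherwise B uniform random permutations are drawn
with p = (exceedances + 1)/(draws + 1), stopping early once 10 exceedances
accumulate — at that point p̂ ≥ 10/401 and can no longer resolve below the
0.01 segregation gate, so further draws are wasted. Ties count as
exceedances by default (conservative); a strict-exceedance mode is
available. No multiplicity correction is applied across terms' empirical
p-values; the segregation call is per-term at p < 0.01.

**Projection.** Group centroids A and B are the arithmetic means of each
group's sample vectors in the set's subspace. For sample P,
alpha_raw = (P−A)·(B−A)/|B−A| and beta = |(P−A) − proj_axis(P−A)|, both in
log2-expression units, satisfying |P−A|² = alpha_raw² + beta². The default
reported alpha is alpha_raw/|B−A|, anchoring group means exactly at 0 and 1
(means of projections equal projections of means) and making rows of the
heatmap comparable across terms; raw alpha is always emitted alongside.
The origin is the first-listed contrast group's centroid. A degenerate axis
(|B−A| = 0) yields alpha = 0, beta = |P−A| and a flag.

## Numerical and design choices

- **Exact small-instance 2-means.** With ≤ 12 samples the optimal
  bipartition is found by enumerating all 2^(n−1) − 1 splits (followed by a
  Lloyd refinement pass, which cannot increase the within-SS), so the
  reported within-cluster SS is the global minimum. Larger instances use
  Lloyd's algorithm with 10 restarts initialized from distinct data points
  of a seeded RNG, tie-broken by lowest within-SS then lowest restart
  index. Identical points are a degenerate case: one effective cluster,
  within-SS 0, logged warning.
- **Determinism.** One global seed drives everything. Each term's k-means
  and permutation stream is seeded by SHA-256 of (seed, term_id) truncated
  below 2^31, so adding or removing terms does not shift other terms'
  results; two runs with the same seed produce byte-identical tables.
- **Exceedance tolerance.** V-measure comparisons in the permutation test
  use a 1e-12 tolerance so that exact ties arising from symmetric label
  arrangements are classified consistently across platforms.
- **Figures are testable.** Every image writes its plotted numbers as a
  sidecar TSV; tests assert on sidecars only. Per-term files follow
  `GSEPD.<groupA>x<nA>.<groupB>x<nB>.GO<digits>.<ext>`, which parses back to
  the contrast and term. Scatter pages pair consecutive genes in sorted
  order, padding an odd set by re-using the first gene. Of the original
  display family this package implements the four figure types and four
  tables described above (HMA, scatter pages, PCA, DE heatmap; DE,
  enrichment, validity, projection tables).

## The synthetic-data generator

`simulate_study` draws counts from a negative binomial with mean
s_j · μ_i · 2^(effect_i · w_j) and dispersion 0.1 (variance μ + 0.1 μ²):
gene baselines μ_i log-uniform in [20, 2000] (typical bulk RNA-seq counts
after library-size differences), sample size factors uniform in [0.7, 1.4],
w_j = 0 in group A, 1 in group B, and a configurable mixing weight (default
0.5) for non-tested samples so their expected alpha is intermediate and
known. The bundled golden study uses 60 genes, 6 tested samples per group
plus 4 non-tested samples, one 10-gene set with log2 effect 4 and four
decoy sets — an effect large enough that segregation is essentially
deterministic, which is what an end-to-end recovery check needs.

What the generator does **not** emulate: gene-length effects, GC/batch
covariates, correlated genes within sets beyond the shared mean shift,
outlier samples, or library-preparation artifacts. Passing tests therefore
demonstrate correctness of the computational pipeline under a clean
negative-binomial world, not robustness to the full messiness of real data;
the external-DE-table path exists precisely so real studies can bring a
count-model-aware test.

Null calibration is checked on a 2500-gene, 500-decoy-set study at 6v6 —
sizes chosen to give a stable Monte-Carlo estimate of the false-segregation
rate while keeping the default test run fast.

## Known limitations

- The Welch default is anticonservative for very low counts and n = 2–3 per
  group; use an external NB-based table there.
- Gene sets are flat: no ontology parsing, no ancestor propagation, no
  parent–child pruning of redundant GO terms.
- k = 2 only, matching the two-group contrast; heterogeneous substructure
  within a group shows up as elevated beta rather than as extra clusters.
- The hypergeometric test ignores selection bias from gene length or
  expression level.
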