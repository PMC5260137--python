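# Methods

## The fuzzy score

Within each sample, genes are ranked in ascending order of intensity
with fractional (mean) ranks for ties, so the rank sum is always
G(G+1)/2 and the transform is permutation-equivariant. The quantile
boundary rank is defined as the real number q(θ) = (1 − θ)·G, never
rounded: this keeps the interpolation exact, independent of any rounding
convention, and bit-reproducible across platforms.

The score is computed as `clip((r − q(θ₂)) / (q(θ₁) − q(θ₂)), 0, 1)`,
which reproduces all three branches of the piecewise definition exactly:
the clipped linear form reaches 1 precisely when r ≥ q(θ₁) and 0
precisely when r ≤ q(θ₂). The boundary case r = q(θ₁) is thereby
assigned to the interpolation branch, whose value there is exactly 1 —
the unique continuous completion of the piecewise definition, and
behaviorally identical to extending the score-1 branch.

Defaults θ₁ = 0.05, θ₂ = 0.15. Values of θ₁ in roughly 5–10% and θ₂ in
15–20% behave similarly in our experience, but both are plain
parameters; no robustness claim is encoded.

Degenerate input: a constant sample leaves every gene at the tied
mid-rank (G+1)/2, so all genes receive one common score from the same
formula. This is logged as a warning rather than raised, so pipelines
survive pathological fixtures; every other transform treats a constant
sample as an error where its definition requires spread (z-score,
scaling by a zero statistic).

## Comparator normalizers

* **Mean/median scaling** multiply each sample by (grand statistic /
  sample statistic), the grand statistic being the mean of per-sample
  means (respectively medians).
* **Z-score** standardizes each sample to mean 0, sd 1, using the
  population (divide-by-n) standard deviation; tests pin this choice.
* **Quantile normalization** replaces each value by the cross-sample
  mean of the sorted values at its rank. Within-sample ties receive the
  mean of the reference values their tied ranks span (the common
  dialect of the tie rule).

## Variance selection and PCA

High-variance selection takes the top ceil(fraction·G) genes by
across-sample variance (population variance; ties broken
lexicographically by gene id so results are deterministic). PCA treats
samples as observations and genes as features, mean-centering features
but *not* scaling them to unit variance — the pipeline deliberately
selects genes by variance, which unit scaling would erase. Component
signs are fixed so the largest-magnitude gene loading in each component
is positive, making coordinates reproducible across linear-algebra
backends.

The "genes with non-zero loading" filter uses a threshold ε (default
1e-12) because dense PCA loadings are never exactly zero; at the default
only structurally zero loadings — constant genes — are removed. ε is
exposed for users who want a sparser reading.

Component specs are explicit everywhere: `first3` (PC1–PC3) for
heterogeneous batch-free data, `pc23` (drop PC1) for batch-ridden data,
reflecting the empirical fact that a dominant batch shift loads on PC1.
Nothing is inferred automatically.

## Evaluation suites

**Quality.** The silhouette statistic, mean over samples of
(b − a)/max(a, b) with Euclidean distance on the PCA coordinates, scores
the *known phenotype labels* — no clustering algorithm is run; the
question is how well the transform separates phenotypes. Singleton
clusters contribute 0 (the standard convention). The observed score uses
the top-variance genes; the null draws random gene subsets of the same
ceil-rounded size, one sub-seed per iteration spawned from the master
seed so individual iterations are independently reproducible.

**Consistency.** Samples are split in half stratified by phenotype only
(batch-stratified splitting is easy to add but off by default); odd
phenotype counts send the extra sample to either half by a seeded coin
flip. Each half is normalized independently; its top-variance genes are
filtered by the non-zero-loading rule on the spec's components, and the
two lists are compared by Jaccard coefficient. Defaults: 100 splits.

**Coherence.** Pathways are undirected graphs; the gene list induces a
subgraph per pathway, and connected components of size ≥ 2 are counted,
aggregated across pathways by size (a gene in two pathways may
contribute to two components; pathways are never merged; singletons are
never counted). The per-size p-value is the proportion of null
iterations whose count at that size *strictly exceeds* the observed
count; strict ">" makes p = 0 attainable, and an optional add-one
smoothing flag is available for users wanting conservative nonzero
p-values. The null redraws uniform random gene subsets (same size as
the observed selection) from the expression matrix's gene universe —
not the pathway universe — and induces directly; p-values are tallied
on raw counts, with percentage frequencies reported separately.

**Sample-size curves.** Phenotype-stratified subsamples at fractions of
the cohort (defaults 0.25/0.5/0.75, 100 iterations), re-normalized and
re-scored per draw; per-phenotype subsample sizes round half-up and must
stay ≥ 2.

## The synthetic generator

The generator emulates merged multi-batch microarray cohorts:

| parameter | default | meaning |
|---|---|---|
| `baseline_log_mean/sd` | 6.0 / 1.5 | natural-log gene baselines (abundances span orders of magnitude) |
| `effect_size` | 8 | fold change of DE genes in their phenotype |
| `de_fraction` | 0.10 | DE genes per non-reference phenotype (disjoint sets) |
| `batch_effect_size` | 1.0 | sd of the per-gene log batch factor |
| `sample_scale_log_sd` | 0.4 | per-array overall brightness factor |
| `noise_log_sd` | 0.25 | multiplicative noise sd for the most abundant genes |
| `cv_low_expression_multiplier` | 3 | noise sd inflation at the lowest abundances (linear in abundance rank) |
| `de_baseline_band` | (0.50, 0.85) | abundance-percentile band DE genes are drawn from |

All distortions are multiplicative (log-normal), keeping intensities
strictly positive and matching how platform- and array-scale biases
manifest. Noise heteroscedasticity makes low-expression ranks unstable,
the regime rank-based methods must cope with.

DE genes are drawn from the mid-abundance band because planted markers
must be *detectable in principle* by a within-sample rank shift: a gene
already saturating the top 5% scores 1 in every sample regardless of
fold change, and a gene deep in the noisy low tail cannot climb into
the scoring region. The planted markers are therefore "induced" genes —
moderately expressed in the reference phenotype, lifted into the top
ranks by the fold change — the classic disease-marker pattern.

Pathway modules are random spanning trees plus extra edges (connected by
construction) whose node sets overlap the DE truth set by a configured
fraction; background pathways are drawn from non-DE genes. Presets:
`two-batch` (2 phenotypes × 2 batches, 10 samples per cell),
`dmd-like` (a merged two-study design, 12+12 and 22+14 samples across
two platforms, at reduced gene count), `heterogeneous` (4 subtypes, one
batch), and `no-signal` (effect 1, batch 0) for calibration. Everything
derives from `SimulationConfig.seed`; identical configs give
byte-identical TSV output.

### What the generator does and does not show

Passing the synthetic suites shows the pipeline recovers planted
structure of the modeled kinds: monotone array/batch distortions,
fold-change phenotype signal in rank-detectable genes, module-structured
pathways. Real data add things the model omits: probe-level artifacts,
correlated gene blocks beyond the planted modules, nonmonotone batch ×
gene interactions, and label noise. Results here bound what the methods
can do under favorable, known-truth conditions; they do not certify
performance on any particular real cohort. On batch-confounded data,
top-variance recovery of DE truth is intentionally *not* asserted:
batch-shifted and boundary-noise genes legitimately compete for
variance, which is precisely the problem under study.

## Problem sizes

Reference runs use 1000 genes and 24–60 samples; null suites in the
packaged tests use 100–200 iterations and the consistency suite 1–20
splits, sizes at which every distributional statement tested (null
quartiles, calibration bands, directional wins across 20 seeds) is
stable while the whole suite stays quick to run. The library defaults
remain 1000 null iterations / 100 splits / 100 subsample iterations.

## Known limitations

* GFS discards absolute expression levels entirely; analyses needing
  magnitudes (dose-response, absolute abundance) should not run on GFS
  scores.
* Scores are piecewise-linear in rank; genes tied across the θ₂
  boundary in a heavily tied sample can share a fractional rank and
  hence a score that straddles neither branch cleanly (the formula is
  applied to the tied rank literally).
* The "non-zero loading" filter is ε-dependent; with the default ε it
  only removes constant genes, so on generic data it is nearly a no-op
  and consistency/coherence results are driven by the variance
  selection.
* PC1 exclusion is a convention, not a detector: if batch effects do
  not dominate PC1 (or biology does), dropping PC1 discards signal —
  the heterogeneous preset illustrates this regime, and the component
  spec must be chosen by the analyst.
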