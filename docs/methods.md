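# Methods

This note documents the statistical procedures behind each metric group,
the defaults that matter, the synthetic-data model used for testing, and
the design decisions taken where the methodology was genuinely open.

## Data model and alignment

A data table is a feature-by-sample numeric matrix with explicit missing
values (`NA`/`NaN`/empty cells; `0` is always a measured value — proteomics
tables routinely distinguish zero intensity from "not observed"). Each
table declares its scale (`raw` linear intensities, non-negative, or
`log2`); the scale is never sniffed from the values, though a table
declared `log2` whose maximum exceeds 50 triggers a non-fatal warning.
Feature identifiers are compared case-sensitively and never mapped between
namespaces.

When several tables are evaluated together they are restricted to the
*intersection* of their sample sets, reordered to annotation order.
Intersection (rather than union with induced missingness) keeps every
correlation-based metric on actually co-measured samples; evaluation
refuses to proceed below 3 shared samples, where correlation is
meaningless. Feature sets are deliberately *not* intersected — the depth
metrics exist to compare per-table feature coverage.

QC replicates (flagged `is_qc`) participate in all technical metrics but
are excluded from class prediction and clustering concordance: they carry
no biological class of interest.

## Group 1 — depth

A feature is **identified** if it has ≥ 1 non-missing value, and
**quantifiable** if observed in at least `quantifiable_min_fraction` of the
samples (default 0.5, configurable). "Quantifiable" has no universal
definition; the ≥ 50%-of-samples rule is the common proteomics convention
and is stated explicitly so the counts are reproducible. Cross-table
overlap uses exclusive (UpSet-style) membership patterns over *identified*
features, so placeholder rows that are entirely missing cannot inflate the
overlap; pattern counts always sum to the size of the union. The
missing-fraction histogram uses right-closed bins on [0, 1] (first bin also
left-closed), so fully observed features land in the first bin and
all-missing features in the last.

The per-sample feature-count scatter is ordered by run order when the
annotation provides one, else by sample position.

## Group 2 — normalization

For each unordered sample pair the AUROC is computed from tie-corrected
rank sums (the Mann–Whitney construction): AUROC(i,j) = P(x_j > x_i) +
½·P(x_j = x_i) over the two samples' non-missing values. This is exact and
deterministic — no classifier is fitted — and satisfies AUROC(i,j) =
1 − AUROC(j,i). Two identically distributed samples give 0.5; a clean
location shift drives the value to 0 or 1.

The AUROC is folded into a per-pair similarity `1 − 2·|AUROC − 0.5|`
(1 = indistinguishable, 0 = perfectly separable) and the table's
similarity score is the unweighted mean over pairs. A perfectly
quantile-normalized table — every sample holding the same value multiset —
attains exactly 1. The aggregation statistic (mean) is a documented choice;
no canonical aggregate exists for this quantity.

Quantiles throughout the package use linear interpolation between order
statistics (numpy's default, the "type 7" rule), so hand checks reproduce.
Samples with fewer than 2 observations are excluded with a warning.

## Group 3 — batch effect

Samples are embedded by PCA: features with missing entries are imputed by
the feature median *for the embedding only*, zero-variance features
dropped, features centered, and component signs fixed so each component's
largest-magnitude loading is positive (coordinates are then deterministic).
Default 10 components are computed (capped at the rank).

Two scalar metrics, both oriented "higher = more batch effect":

- **Average silhouette width** of the batch labels, Euclidean distance in
  the space of the first `silhouette_components` PCs (default 2, matching
  the 2-D PCA view the metric accompanies). Standard silhouette
  s(i) = (b−a)/max(a,b); singleton clusters contribute 0. Working in PCA
  space rather than the raw feature space makes the metric robust to
  imputation noise on sparse features.
- **Principal-component regression (PCR)**: for each leading component,
  the R² of a one-way ANOVA of the PC scores on the batch factor
  (between-group SS / total SS); components are weighted by their variance
  fractions. By default the leading components covering ≥ 80% of variance
  enter, capped at 10 — mirroring principal-variance-component-analysis
  practice. Under random grouping E[R²] = (g−1)/(n−1), so the null value is
  near zero for realistic n.

The report maps both to quality scores as `1 − clamp(metric, 0, 1)`.
Sample–sample Pearson correlation (for the heatmap) uses pairwise-complete
observations; pairs sharing < 3 features are reported missing, not
fabricated.

## Group 4 — biological signal

**Complex-pair correlations.** Intra-complex pairs (both members share ≥ 1
complex) and inter-complex pairs are sampled in equal numbers (default
200, seeded). An inter pair requires both members to be annotated to some
complex while sharing none — matching the null on annotation coverage
rather than drawing from all features. Pearson r is computed per pair on
pairwise-complete observations (≥ 6 required). The scalar summary is the
AUROC of r discriminating intra from inter pairs (0.5 = no co-expression
signal).

**Network function prediction.** The co-expression network connects each
quantifiable feature to its `network_top_k` (default 10) highest-|r|
partners (pairwise-complete Pearson, pairs with < 6 shared observations
excluded), symmetrized by union, edge weight |r|. The random walk with
restart iterates p ← (1−r)·Mp + r·p₀ with M the column-normalized
adjacency, p₀ uniform on the seed set, restart r = 0.5, L1 tolerance 1e-6,
max 1000 iterations; mass on zero-degree nodes is redistributed to p₀, so
the score vector remains a probability distribution. A pathway is eligible
with ≥ max(5, cv_folds) members in the network; its members are split into
`cv_folds` folds (default 5, seeded), each fold's held-out members are
scored by a walk seeded from the remaining members, and held-out and
negative scores are pooled across folds (negatives re-entering once per
fold) into one tie-aware AUROC. The table summary is the median over
eligible pathways.

**Class prediction.** Exactly two class levels, each with ≥ `cv_folds`
samples. Features: top 500 quantifiable features by variance. Median
imputation and standardization are fitted inside each training fold; the
model is logistic regression with fixed L2 regularization (C = 1);
stratified `cv_folds`-fold CV with seeded shuffling; the reported AUROC is
computed on the pooled out-of-fold scores. The model family is a
deliberate, swappable baseline — the aim is comparing tables, not
maximizing accuracy, so a fixed simple learner is the fair instrument.

**Clustering concordance.** Average-linkage hierarchical clustering on
distance 1 − Pearson r (pairwise-complete), cut at k = number of class
levels; adjusted Rand index against the class partition (high = biology
drives grouping) and the batch partition (high = batch drives grouping).

## Group 5 — platform reproducibility

Per-feature CV = sample SD (n−1 denominator) / mean across the QC
replicate samples, on the **linear** scale — log2-declared tables are
back-transformed (base configurable, default 2) first, since CV of log
intensities is not the conventional reproducibility measure. Features with
< 2 QC observations or non-positive mean are excluded and counted. The
headline metric is the fraction of features with CV below the threshold
(default 0.30). Requires ≥ 2 QC replicates; otherwise the group is
reported as skipped, never silently zero.

## Group 6 — multi-omics concordance

Gene-wise (per shared feature, across shared samples) and sample-wise (per
shared sample, across shared features) correlation between the table and a
paired table from another omics layer. Spearman rather than Pearson,
because cross-omics abundance relationships are monotone but rarely
linear. Each correlation needs ≥ 6 complete observation pairs; the group
needs ≥ 10 shared features and ≥ 6 shared samples. The summary is the
median gene-wise r. The computation is symmetric in the two tables.

## Radar scores

The mapping from raw metrics to the [0, 1] radar scale is fixed and
recorded in the report (`mapping_record`) so comparisons are auditable:
depth = n_quantifiable / max over tables; normalization = similarity
score; batch = mean of (1 − clamp(ASW, 0, 1)) and (1 − PCR R²); signal =
mean of the available AUROCs rescaled from [0.5, 1] to [0, 1] with
clamping; reproducibility = fraction of CVs below threshold; concordance =
clamp(median gene-wise r, 0, 1). Groups that could not be computed are
absent, never zero, so a missing QC design does not punish a table.

## Synthetic-data generator

All tests run on generated data; the generator emulates a log2-intensity
study with the structures the metrics are designed to detect:

- per-feature baseline N(20, 2²) log2 units;
- `n_modules` co-expression modules of `module_size` features: a shared
  per-sample latent N(0, module_latent_sd²) plus feature noise
  N(0, noise_sd²), giving a closed-form intra-module correlation
  latent²/(latent² + noise²) (defaults 1.0 and 0.5 → r = 0.8, a tight
  protein-complex regime); module membership doubles as the complex and
  pathway annotation;
- background features i.i.d. with matching total variance, occupying the
  leading rows; the class effect (default 2.0 log2 units, about 2× the
  per-feature SD, on the first 20 features) therefore lands on independent
  features rather than riding on a module latent — this keeps the class
  signal and the co-expression signal orthogonal, so degrading a table
  degrades both monotonically;
- a two-level class alternating with run order and contiguous batch
  blocks, so class and batch are near-orthogonal; an optional uniform
  `batch_shift` (log2 units) on non-reference batches;
- pooled-reference QC replicates (baseline + N(0, 0.2²), about 14% linear
  CV — a realistic well-behaved platform), assigned round-robin to
  batches;
- missing entries completely at random (MCAR, default 5%); MCAR keeps the
  closed-form checks valid — intensity-dependent missingness is exactly
  the kind of structure real proteomics data adds on top;
- a paired table = table + independent N(0, 1) noise.

Default size: 300 features (4 modules × 20 + 220 background) × 40 study
samples + 4 QC replicates. Everything derives from a single seed;
identical specs produce byte-identical files.

**What passing these tests does and does not show.** The generator
produces Gaussian, MCAR, module-structured data; real tables have
intensity-dependent missingness, heavy-tailed abundances, correlated
batch × class designs and annotation errors. Passing shows the metrics
recover planted structure of realistic magnitude and respect their exact
invariants — not that any particular real dataset will score well.

## Numerical choices

- AUROCs are computed from tie-corrected rank sums — exact, no fitted ROC.
- PCA signs fixed by the largest-|loading| rule; degenerate (all-constant)
  matrices are rejected rather than embedded as zeros.
- RWR convergence: L1 < 1e-6 (default) or 1000 iterations; on every ≤
  8-node network the iterate matches the direct solve
  p = r(I − (1−r)M)⁻¹p₀ to 1e-6 (tested).
- Correlations on pairwise-complete data require ≥ 3 (sample-level
  heatmap) or ≥ 6 (feature-level metrics) shared observations; scarcer
  pairs are reported missing with a warning.
- Sample SD uses the n−1 denominator everywhere.
- All stochastic steps (pair sampling, fold assignment) take their seed
  from `EvaluationConfig.random_seed`; identical config + seed gives
  byte-identical TSV outputs (tested).

## Problem sizes used in the automated checks

The test and acceptance runs use the generator at its default scale
(300 × 44) or smaller (down to 100 features × 24 samples for the 25-seed
batch-shift sweep), sizes at which every closed-form and oracle comparison
is exact or tight while a full two-table evaluation completes in seconds.
Metric behaviour does not depend on scale beyond sampling noise, which the
seed-averaged checks account for.

## Known limitations

- Class prediction is two-class only; multi-class designs are rejected.
- No batch *correction*, normalization, or imputation is performed — the
  tool evaluates tables exactly as given.
- No identifier mapping: tables and gene sets must share a namespace.
- The inter-complex null requires features annotated to ≥ 1 complex; with
  a single complex covering all annotated features no inter pair exists
  and the metric is skipped.
- The radar normalization is implementation-defined (recorded in the
  report); scores are comparable within a report, not across tools.
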