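# Methods

This note documents what `scperf` computes, the default parameters, what
the synthetic generator emulates, and the open design decisions.

## 1. Pipeline grid

A pipeline is an ordered composition applied to a raw genes × cells count
matrix:

**Cell QC.** Per-cell metrics in the style of `scuttle::addPerCellQC`:
total counts, detected features and their log10 values, the percentage of
counts in the top 20/50/100/200 expressed features, the mitochondrial count
proportion, and `featcount_dist` — the residual of log10 detected features
against log10 total counts under a local (tricube, degree-2, span-0.75)
regression. Cells with zero totals are flagged.

**Filtering (MAD rules, constant 1.4826).** A cell accrues outlier flags:

- log10 totals or log10 features below `median − 5·MAD` or above
  `median + 2.5·MAD`;
- top-20% fraction and `featcount_dist` outside `± 5·MAD`;
- mitochondrial proportion above `median + 2.5·MAD` **and** above 0.08.

*default* removes cells with ≥ 2 flags; *stringent* removes cells with
≥ 1 flag; *lenient* uses `± 5·MAD` bounds throughout, a mito rule of
`median + 3·MAD` **or** > 0.08, and removes at ≥ 2 flags.

**Normalization.** (a) *lognorm*: `log1p(1e4 · x / libsize)`;
(b) *pooling*: deconvolution size factors from overlapping ring pools of
size 20 — pool ratios against a mean reference cell solved as a sparse
least-squares system (LSQR) with weight-0.1 anchor equations, factors
mean-normalized, then log-normalization with those factors; (c) *pearson*:
analytic Pearson residuals under a negative-binomial null with θ = 100,
clipped at ±√n_cells.

**Feature selection.** 2,000 highly variable genes by the variance-
stabilizing procedure: local regression of log10 variance on log10 mean of
the **raw counts** of kept cells, standardization by the predicted sd,
upper clipping at √n_cells, ranking by the variance of the clipped values.
The normalized matrix is then subset to those genes.

**Dimensionality reduction.** PCA by thin SVD of the standardized matrix,
with the sign convention that each component's largest-magnitude loading is
positive; 10, 15, 20 or 30 components.

**Clustering.** Shared-nearest-neighbour graph (k = 20 including self,
Jaccard weights `c/(2k − c)`, pruned below 1/15) and igraph Louvain
(`community_multilevel`) at resolutions 0.1, 0.2, 0.3, 0.5, 0.8, 1.0, 1.2,
2.0 with a seeded generator.

3 × 3 × 4 × 8 = **288 pipelines**. `run_grid` caches shared stages (QC per
dataset; filtering; normalization; embedding) so the grid costs far less
than 288 independent runs. Pipeline failures become error records, scored
as missing and median-imputed downstream.

## 2. Metrics and the performance table

Purity metrics operate on log1p raw counts of kept cells restricted to the
top 500 HVGs: Calinski-Harabasz `[B/(k−1)]/[W/(n−k)]`, Davies-Bouldin
(stored negated), mean silhouette (singleton clusters score 0). All three
are hand-implemented and tested against independent brute-force formulas
and scikit-learn to 1e-8.

The GSEA metric ranks genes per cluster by one-vs-rest
`log2((mean_in + 1)/(mean_out + 1))` of log1p counts, computes a weighted
Kolmogorov-Smirnov enrichment score (weight `|stat|^1`), normalizes by the
mean |ES| of same-sign gene-label permutations (default 1,000), filters
sets to an intersection size strictly between 10 and 500, and averages
|NES| over sets then over clusters.

Per metric, the long table (`dataset_id × pipeline_id`) gains three stages:
`_scaled` (within-dataset z-score, ddof = 1), `_corrected` (residual of a
per-dataset local regression on k — applied to the purity metrics; the GSEA
metric is scale-only by default, switchable via `correct_gsea`), and
median imputation of missing entries per dataset with an `_imputed` flag.

## 3. Dataset features

21 QC summaries per dataset (medians and MADs of per-cell metrics, cell and
gene counts, sparsity, library-size CV and skewness, mito/coding gene
fractions, fraction of high-mito cells) plus q = 20 scores from a
closed-form maximum-likelihood probabilistic PCA (Tipping & Bishop; 1/N
eigenvalue convention; σ² = mean of discarded eigenvalues; posterior scores
`(WᵀW + σ²I)⁻¹Wᵀ(x − μ)`) of the dataset-by-gene mean-expression matrix.
PPCA and the feature z-scalers are fitted on training datasets only and
applied unchanged to held-out datasets (no leakage).

## 4. Meta-learning

Feature modes: *pipeline_only* (4 pipeline parameters) and *interactions*
(41 dataset features + pipeline parameters = 45 columns for trees; for the
elastic net the pipelines are one-hot encoded and the full dataset ×
pipeline product terms are appended, 41 + 8 + 328 = 377 columns). The
target is the corrected (fallback: scaled) metric.

Tuning grids: random forest ntree ∈ {100, 300, 500}, mtry ∈
{1, ⌈p/3⌉, ⌈p/2⌉, p}; elastic net mixing α ∈ {0.10, 0.55, 1.00}, penalty
λ ∈ {0.001, 0.01, 0.1} (scikit-learn `ElasticNet(alpha=λ, l1_ratio=α)`).
Model selection minimizes pooled RMSE under 10-fold dataset-aware CV
(balanced round-robin partition of training datasets).

The dataset-aware 70/30 split forces labeled datasets into the test set
(e.g. 86 datasets with 16 labeled → 61 train / 25 test).

## 5. Evaluation

Per held-out dataset: Pearson r between predictions and the observed
corrected metric across its pipelines (≥ 3 pipelines required). Across
test datasets: one-sample Wilcoxon signed-rank test, alternative "greater
than zero" (exact when possible), Benjamini-Hochberg adjusted across the
16 metric × model × mode blocks. For labeled datasets the same correlation
is computed against the pipeline-wise adjusted Rand index versus the
reference labels. Determinant analysis correlates each dataset feature
with per-dataset predictive power (two-sided Pearson test, α = 0.05).

## 6. Synthetic data

**Count generator.** Gamma-Poisson (negative binomial, θ = 2 by default;
θ → ∞ recovers Poisson) around per-cluster expression profiles: a shared
lognormal(0, 1.5) base profile, per-cluster DE genes (probability
`de_prob`, log2 fold changes ~ N(0, `logfc_sd`)), mitochondrial genes
rescaled to a 5% expression share (30% in a 5% fraction of outlier cells),
log-normal library sizes (meanlog = log 5000, sdlog = 0.35). Defaults: 500
cells, 1,500 genes, K = 4 clusters, 2% mito genes, 80% coding. It emulates
the moments and planted-structure aspects of splatter-style simulators; it
does **not** model batch effects, doublets, gene-gene correlation beyond
cluster structure, or dropouts beyond NB sampling.

**Planted performance tables.** `value = F·βd + G·βp + F·B·Gᵀ + noise`
with dataset features F and one-hot pipeline encoding G, giving exact
ground truth for meta-model recovery experiments.

Seeding uses `numpy.random.SeedSequence` spawning throughout; all seeds are
masked to < 2³¹.

## 7. Numerical and design decisions

- **Local regression** is a self-contained tricube-weighted polynomial
  (degree 2, span 0.75) in `scperf.smooth`; no installed dependency offers
  a loess predictor with this exact behavior.
- **HVG selection runs on raw counts** of the filtered cells (then subsets
  the normalized matrix): the variance-stabilizing trend assumes
  nonnegative count-like input and breaks on Pearson residuals.
- **"lenient" filtering** keeps the two-flag removal rule but relaxes every
  bound; "stringent" removes on any single flag, so its removed set is a
  superset of default's (property-tested).
- **Significance vs zero** uses the one-sample Wilcoxon *signed-rank* test
  (the natural one-sample reading of a rank test against 0).
- **GSEA aggregation** is mean |NES| over sets, then mean over clusters;
  `agg="max"` is available.
- **Correction order** is scale-then-correct: residuals of the z-scored
  metric on k, so corrected values stay on a comparable within-dataset
  scale.
- **Dropped values** (failed pipelines, k = 1 outputs) are median-imputed
  within dataset *after* correction and flagged.
- The 21-feature QC schema is fixed in `scperf.features.QC_FEATURE_NAMES`
  and asserted at runtime.
- Desk-scale default study: 6 datasets × a 36-pipeline subgrid (all
  filtering × all normalization × 10 dims × 4 resolutions), PPCA q = 2,
  2-fold CV — every stage exercised end to end in ~2 minutes, deterministic
  under a fixed seed. Full-scale problem sizes (86 datasets × 288
  pipelines, q = 20, 10-fold CV) are reachable purely through
  `StudyConfig`.
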