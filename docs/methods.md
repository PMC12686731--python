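# Methods

## Synthetic cohorts

The single-cell generator draws counts gene-by-cell from a negative
binomial parameterized by (mean, dispersion θ) with variance μ + μ²/θ,
via the gamma–Poisson mixture. The per-cell mean is a product of:

- a log-normal baseline per gene, `exp(N(baseline_mean_logmu,
  baseline_mean_logsd))` (defaults −1, 1 — a sparse CP10K-scale
  transcriptome);
- a marker boost `2^marker_log2fc` applied to each subtype's disjoint
  marker block in that subtype's cells only;
- a per-(batch, gene) multiplicative factor `exp(N(0, batch_effect_sd))`
  (default sd 0.15) — the simplest structure the optional log-space batch
  centering removes exactly;
- an age trend `exp(±trend_slope · age_code)` on each planted trend set,
  with ordinal age codes fetal = 0, adult = 1, elderly = 2 and alternating
  planted signs;
- a per-cell library-size factor `exp(N(0, 0.3))`, giving a realistic
  sequencing-depth spread for the normalization stage to remove.

Marker and trend genes are placed at seeded-random positions in the gene
universe. This matters: per-cell rankings break expression ties by gene
symbol, and a contiguous, lexicographically early marker block would be
systematically favored among tied (mostly zero) values, biasing every
rank-based statistic downstream.

Default dispersion is θ = 2 (coefficient of variation ≈ 0.7 for the
biological rate), within the range typical of UMI data. Identical configs
including the seed reproduce matrices bit-for-bit.

What the generator does **not** emulate: doublets, ambient RNA,
cell-cycle structure, UMI saturation, gene–gene correlation beyond the
planted blocks, or realistic gene-symbol vocabularies. Tests passing on
these cohorts demonstrate that each statistic recovers the structure it
is designed for at realistic noise levels — not that the pipeline's
thresholds are optimal for any particular real tissue.

The bulk generator ties survival to a latent per-sample signature
activity z ~ N(0,1): signature genes' log-expression shifts by
`enrichment_effect · z`, and event times are exponential with hazard
`baseline_hazard · HR^z` (optionally times `exp(effect · covariate)`).
Censoring is decided by an independent Bernoulli(censor_rate) coin; a
censored sample reports a uniform time before its event. Trait gene
lists draw a controlled fraction of a target set plus uniform background,
so overlap under the null follows the hypergeometric law exactly.

## QC

Filters run in a fixed order, once: samples with fewer than
`min_cells_per_sample` cells (default 2000) are dropped; then genes
expressed in fewer than 3 cells; then cells with fewer than 200 expressed
genes or a mitochondrial count fraction above 0.20 (computed on pre-filter
counts over `MT-`-prefixed symbols — the threshold is a convention and is
exposed as a parameter). A single pass is idempotent on its own output.
Normalization scales each cell to 10,000 counts and applies log1p; raw
counts are kept alongside. HVGs are ranked by the variance of
log-normalized expression z-scored within 20 mean-expression bins;
constant genes rank last and ties break by symbol, so selection is
deterministic and invariant to cell order.

## Per-cell NES

For each cell, genes are ranked by normalized expression (descending,
symbol tie-break). The enrichment score is a weighted Kolmogorov–Smirnov
running sum: in-set steps are weighted by |expression|¹ (normalized to the
set's total), out-of-set steps are uniform; ES is the running sum at its
maximal absolute deviation. NES divides ES by the mean positive ES over
`n_permutations` gene-label permutations (default 200), with the same
permuted sets shared across cells — a deterministic, seeded null. Cells
expressing no marker fall back to unweighted in-set steps. NES is
invariant to positive rescaling of a cell's expression vector.

## Cluster purity

Within a cluster, each gene contributes E = log(mean expression + 1) and
S = the entropy of its expression distribution across the cluster's cells
(pᵢⱼ = xᵢⱼ/Σⱼxᵢⱼ, natural log, 0·log 0 = 0). A homogeneous gene has S
near the value expected for its E; expression concentrated in a
subpopulation depresses S. The baseline Ŝ(E) is a LOESS fit (span 0.5)
across genes, and the purity statistic is 1 − D/(D + K) with K = 45 and
D the summed significant entropy deficit max(0, Ŝ(E) − S).

Three numerical choices keep D honest:

- **Expression floor.** Genes below mean expression 1 (CP10K scale) are
  excluded. Their entropy estimates carry a heavy right-skewed sampling
  tail (a gene seen in a handful of cells always looks "concentrated")
  that otherwise dominates D in perfectly homogeneous clusters.
- **Trimmed refit.** After the first fit, genes more than 2.5 local-sd
  below the curve are set aside and the baseline refit (twice). Without
  this, a large planted heterogeneity band drags the baseline onto
  itself and hides.
- **Empirical mirrored null.** Deficits are scaled by a local
  (E-dependent) sd estimated from the non-deficient genes, and one-sided
  p-values come from the empirical distribution of the mirrored
  non-positive residuals, BH-adjusted at 0.05. A single extreme gene
  cannot reach significance on its own, so homogeneous clusters score
  exactly 1.0; a genuine heterogeneity band (tens of genes) is called in
  full. A normal-approximation test was tried first and carried a
  systematic small-cluster power bias — smaller clusters looked purer —
  which inverted merge decisions.

Because homogeneous groups saturate at exactly 1.0, the purity-gain merge
accepts ties (merged purity ≥ both parents): an exact tie means no
detectable heterogeneity was created by merging. Clusters under 20 cells
report purity as missing. When sample labels are available, a merged
cluster's purity is the average over samples holding ≥ 20 of its cells.

## LISI

Batch mixing is summarized per cell as the inverse Simpson index of
weighted batch proportions over the 3×perplexity nearest neighbors, with
Gaussian kernel weights calibrated to the target perplexity (default 30)
by bisection. The Simpson sum uses the unbiased weighted estimator
(Σp̂² − Σw²)/(1 − Σw²); the plug-in estimator is biased upward by Σw²
(≈ 0.05 at perplexity 30), which would understate mixing by ≈ 0.1 of an
effective batch.

## Refinement

The kNN graph (k = 15) is built on the top 30 principal components of the
HVG log-normalized matrix; communities come from Louvain-style modularity
optimization (RB-configuration, seeded) at each grid resolution
(0–3, step 0.1). The selected resolution maximizes median cluster purity
(first maximum on ties); LISI is reported alongside. Purity, DEGs, and
merge decisions are computed on the **full** gene set: HVG selection
skews the gene composition the entropy baseline relies on.

DEGs are one-vs-rest Wilcoxon rank-sum tests with log2 fold change of
mean(expm1(normalized)) + 1, kept at log2FC > 1 and BH-adjusted p < 0.01,
ranked by log2FC (ties by adjusted p, then symbol). Shared-DEG merging
connects clusters sharing ≥ 5 of their top-20 DEGs, merges connected
components, recomputes DEGs, and repeats to a fixpoint. Purity-gain
merging then greedily merges the most-correlated (Spearman of mean
profiles) pair whose union is at least as pure as both parents,
recomputing after every merge.

## Module scores and downstream tests

A module score is the mean normalized expression of the set minus the
mean of control genes: genes are binned into 24 bins by average
expression and each set gene draws 100 controls (with replacement) from
its bin, excluding set genes; the draw is seeded. Adding δ to every set
gene adds exactly δ to every score as long as bin assignments are
unchanged.

Normal-like vs CAF-like grouping uses a paired two-sided t-test of the
two scores per subtype (BH across subtypes; the group follows the larger
mean, exact ties report "indeterminate"). State correlations are Spearman
per unordered pair per subtype. Composition enrichment uses 2×2
chi-square with continuity correction, falling back to Fisher's exact
test when any expected count is below 5.

Age trends are per-set OLS regressions of the module score on the ordinal
age code; the slope's t-statistic partitions sets at |t| > 30 (an exact
zero-residual fit reports t = ±∞; a zero-variance score reports t as
missing). Signatures are exact set unions with per-gene provenance; the
overlap between the senescence and stemness signatures is reported, not
removed. Age-group enrichment is one-sided Fisher per (tissue, subtype,
age group) with a 100-cell condition floor; score comparisons are Welch
t-tests under the same floor, BH-adjusted.

## Bulk association

Single-sample enrichment is the rank-weighted running-sum statistic: with
genes ranked descending, the gene at position i carries weight
(N − i + 1)^α (α = 0.25); the score sums the weighted in-set ECDF minus
the unweighted out-of-set ECDF over all positions, then rescales per set
to [−1, 1] across samples. It is invariant to monotone transforms of a
sample's expression; α = 0 recovers the unweighted KS-style sum. Note the
statistic is compositional: a signature genuinely rising across samples
depresses the ranks — and scores — of other signatures, which can appear
as mirrored protective associations in the survival screen. Bulk input is
log10(x + 1)-transformed.

Samples split into "high" (score strictly above the per-set mean) and
"low" (ties to low; an all-one-side split is flagged degenerate). The
log-rank test is implemented from the risk-set definition: at each
distinct event time, observed group-1 events versus their expectation
under the proportional null; the statistic is χ²(1) and the hazard ratio
is the O/E estimator (O₁/E₁)/(O₂/E₂) with log-HR variance 1/E₁ + 1/E₂.
The Cox model is a partial-likelihood fit (lifelines); constant
covariates and non-convergent fits yield flagged rows. Trait overlap is
one-sided Fisher's exact on (trait top-k × subtype DEGs) over a stated
gene universe, reporting raw p (the screening criterion) with BH added;
method concordance is a one-sided Fisher test on the 2×2 table
[[|A∩B|, |A\B|], [|B\A|, n − |A∪B|]].

## Problem sizes

Tests and the acceptance script run at desk scale: 800–2000 genes,
1200–5000 cells, 50–200 NES permutations, 100-replicate null simulations,
400–500 bulk samples. The refinement recovery study uses 5 planted
subtypes × 60 markers at log2FC 2 in a 2000 × 5000 cohort — sizes chosen
so every planted effect is comfortably above the statistics' detection
floors while each stage completes in minutes on one CPU.

## Known limitations

- The purity statistic's detection power degrades when a heterogeneity
  band dominates the high-expression end of the S–E plane (≈ half the
  well-expressed genes, e.g. a 50/50 mixture of two very strongly
  separated subtypes): the trimmed refit can no longer identify the
  baseline. At the planted effect sizes used here this regime is not
  reached.
- Batch centering removes additive log-space offsets only; it is not an
  embedding-based integration method.
- The single-sample enrichment statistic is ssGSEA-style, not the
  Gaussian-kernel GSVA variant; for mean-split stratification the two are
  monotone-equivalent in the regimes exercised here.
- The external cell-type classifier is consumed through a pluggable
  label interface (`mock:<tsv>` or a shell command); no trained model is
  bundled.
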