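# Methods

This note documents the statistical models implemented in `translatomix`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Experimental design

A study has two conditions (control, experiment; labels are user-supplied
identifiers and may not begin with a digit, so downstream class names stay
syntactically valid) and 1 + K fractions: total cytoplasmic RNA
("transcription", fraction 0) and K ≥ 1 polysome fractions. Every sample
belongs to exactly one condition × fraction class and every class must be
non-empty; at least one residual degree of freedom (samples − 2(K+1) ≥ 1)
is required so gene-wise variances are estimable.

Classes are ordered canonically — control before experiment, transcription
before polysome fractions, fraction index ascending, samples within a
class by identifier — so the targets (indicator) matrix, the contrasts
matrix and all downstream tables are fully reproducible regardless of the
input column order. The K+1 contrasts are experiment − control per
fraction, transcription first.

## Normalization (counts)

* **Read filter.** Genes are kept when their count strictly exceeds a
  threshold (default 256) in every sample of a chosen subset. The subset
  defaults to the transcription samples in the pipeline: the filter's
  purpose is to exclude genes whose mRNA-level quantification is unstable,
  and polysome fractions of poorly translated genes are legitimately near
  zero. The subset is exposed for users who want the filter over all
  samples.
* **TMM scale factors.** Reference column = the sample whose 75th
  percentile of library-scaled counts is closest to the mean of those
  percentiles. Per sample, the factor is 2 to the precision-weighted mean
  of log2 ratios against the reference after trimming 30% of ratios (M)
  and 5% of intensities (A) on each side; weights are the delta-method
  (binomial) variances of M. Factors are rescaled to geometric mean 1.
  These are the standard defaults of the trimmed-mean scheme; the
  implementation agrees with the established R implementation to ~1e-5.
* **log-CPM.** `log2((count + 0.5) / (lib × factor + 1) × 1e6)` — prior
  count 0.5 keeps zeros finite while biasing low counts minimally.
* **Precision weights.** Gene-wise least-squares fits of log-CPM under the
  targets design give residual sds; a LOWESS trend (span 0.5, 3 robustness
  iterations) of √sd against average log2 count is interpolated at each
  observation's fitted log-count (flat extrapolation beyond the observed
  range) and the weight is the inverse fourth power of the prediction.
  This converts the count mean–variance relationship into weights an
  ordinary weighted linear model can use.

Microarray input is taken as already background-corrected and log2-scale:
no scaling, unit weights. A maximum above 50 triggers an "un-logged?"
warning and an explicit `log2_transform` helper; nothing is transformed
silently. Validation rejects fractional or negative values on the counts
path, because both TMM and the NB model require raw counts (TPM / RPKM /
FPKM inputs are refused rather than mis-analysed).

## Moderated linear model

Per gene, weighted least squares under the class-indicator design;
contrast estimate β̂ and unscaled standard error u = √(cᵀ(XᵀWX)⁻¹c).
Gene-wise residual variances s²_g on d_g = n − rank(X) df are moderated by
empirical Bayes: log s²_g is moment-matched to a scaled-F model, with the
prior df d₀ obtained by trigamma inversion of the excess spread of
log s²_g over its χ² sampling spread and the prior variance s₀² from the
corrected mean. If the observed spread does not exceed the sampling spread
the prior is infinite (single shared variance); if the variances are
numerically identical the prior is a point mass at that value (no
sampling-bias correction applies to a degenerate sample). The posterior
variance is s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), the moderated t is
β̂/(u·s̃_g) on d₀ + d_g df (normal when d₀ = ∞). As d₀ → 0 this reduces to
the ordinary t; as d₀ → ∞ to a pooled-variance z — both limits are
regression-tested.

## Negative-binomial GLM

Per-gene log-link NB GLMs with offsets `log(lib × TMM factor)` are fitted
by iteratively reweighted least squares, vectorized across genes (batched
normal equations; step-halving on likelihood decreases; ridge 1e-6 on
singular steps; max 50 iterations, relative log-likelihood tolerance
1e-8). Non-convergent genes get NA statistics rather than crashing the
run, as do genes with zero counts across a contrast's classes (their logFC
is undefined).

Dispersion: the common value maximizes the Cox–Reid adjusted profile
likelihood (penalty ½ log det XᵀWX) pooled over genes, optimized on
log10 φ ∈ [−6, 0.7]; per-gene values then maximize the weighted likelihood
APL_g + (10/d_g)·mean(APL) over an 11-point grid spanning the common value
by ±5 doublings, which shrinks gene-wise estimates toward the common one
with a prior weight equivalent to 10 residual df. Dispersions are floored
at 1e-6. Contrasts are tested by likelihood-ratio: the reduced model
projects the design onto the null space of the contrast, and the LR
statistic is referred to χ²₁. The LRT variant was chosen as the single
well-tested test per engine; it is mildly liberal at n = 3 per class
(matching the reference implementation's LRT to the third decimal on
identical data) — a known property of the test, not an implementation
artifact.

## Translational efficiency

Two estimators of the same quantity, the condition-dependent change in
polysome loading beyond the mRNA-level change:

* **ratio** — per replicate, log2(polysome) − log2(total) (log-CPM on
  counts), replicates paired by identifier order within class (an
  explicit pairing can be imposed by subsetting columns; unequal replicate
  counts are an error rather than a guess). The experiment − control
  contrast of ratios is tested with the moderated machinery and unit
  weights — a ratio of counts is no longer count-distributed, so count
  precision weights would be wrong.
* **interaction** — per fraction, the model
  `intercept + type + treatment + type:treatment` over the transcription
  plus fraction-k samples, with type = 1 for polysome, treatment = 1 for
  experiment (reference cell control/total). On counts the fit uses TMM
  factors and precision weights computed on that sample subset. The
  moderated statistic of the interaction coefficient is the TE test. All
  four type × treatment cells must be populated or the interaction is
  unidentifiable.

On noiseless balanced data the two return identical TE logFC (verified to
1e-9); the interaction method is the default on counts because it keeps
the observation-level weighting.

The multi-fraction TE heatmap displays the **polysome** log2FC of
TE-significant genes (union over fractions), not the TE logFC itself: TE
selects genes whose translation changes beyond transcription, but the
polysome fold change is the more directly interpretable quantity, and
showing all fractions for every selected gene exposes heterodirectional
shifts across the gradient.

## Regulation classification

Gates are strict: |log2FC| > lfc AND p < p_cut (raw p by default,
adjusted by flag); defaults lfc = 1, p_cut = 0.05. lfc = 0 disables the
fold-change gate entirely (p-only selection). Translation significance is
the union over fractions; the representative translation logFC is the
largest-magnitude logFC among the gene's significant fractions (ties to
the lowest fraction index). Buffering is operationalized as
transcription-significant AND translation-not-significant — no
magnitude-gap criterion is imposed. The same/opposite split uses the sign
product of the transcription and representative translation logFC (zero
counts as same-direction). Classification runs on the transcription
table's gene universe; translation-only genes missing from it (different
upstream filtering) trigger a warning and are dropped rather than
silently mixed in. Categories partition the gene set by construction.

## Synthetic studies

The generator emulates a two-condition polysome-profiling study:
2 × (1 + K) classes × n replicates. Counts are gamma-Poisson (NB) with
mean `lib_scale_j × 2^(baseline_g + effect_gj)` and dispersion φ;
the per-sample scale is set so an all-baseline sample totals the drawn
library size and is *not* renormalized per sample, so planted effects are
exactly expected fold changes. Microarray studies draw Gaussian log2
intensities (residual sd 0.3) around the same means. Defaults: 2000
genes, K = 2, n = 3, libraries log-uniform on [0.5M, 1.5M], baseline
log2 abundance ~ N(4, 2), φ = 0.1 (squared biological CV typical of
cell-line replicates), 4-fold (|log2FC| = 2) planted effects, category
proportions 70/10/10/5/5% (unregulated / buffered / translation-only /
concordant / opposite). Buffering is simulated as a transcription shift
with zero net polysome change — the only reading consistent with the
category's definition. Signs are random per gene; everything is
deterministic given the seed.

What the generator does **not** emulate: batch effects, GC/length biases,
probe-level artifacts, fraction-specific library chemistry, positional
footprint structure, or gradient shifts between fractions (each fraction
gets an independent planted effect, not a density trajectory). Passing
recovery tests therefore demonstrates correctness of the inference under
the NB/Gaussian model, not robustness to those real-data artifacts.

A note on bias measurement: in any single simulated study, which genes
carry effects shifts the library composition, and the TMM estimate of
that shift carries a small study-level error (~0.02–0.08 log2 with 30%
contamination at 4-fold) that is shared by all genes of a class. Bias of
the TE estimator is therefore measured as an average over replicate
studies; a single study confounds estimator bias with this wobble. The
same wobble exists in real experiments and in the reference R
implementations, which this package matches numerically.

## Numerical choices

* Trigamma inversion by Newton iteration from x₀ = 0.5 + 1/y.
* BH adjustment is the step-up with cumulative-minimum monotonicity
  enforcement, applied within each contrast separately (selection is also
  per contrast; a global variant is a one-line change on the combined
  table).
* Classical (metric) MDS by eigen-decomposition of the double-centered
  squared leading-logFC distance matrix; leading-logFC distances use the
  top 500 largest per-pair absolute log-fold changes by default.
* All fold changes are reported in log2 units everywhere, including the
  NB path (natural-log coefficients divided by ln 2).
* Result tables are written as tab-delimited UTF-8 with 6 significant
  digits; figures are written as PDF + PNG with the plotted numbers in a
  sidecar TSV.

## Problem sizes

Benchmarks and acceptance checks run at G = 2000 genes, K = 2 fractions,
n = 3–4 replicates — the scale of the studies the pipeline targets — with
the type-I checks pooling p-values across contrasts (n = 4000–6000 tests)
and the TE bias averaged over five replicate studies. The full test suite
runs in well under a minute on one CPU.

## Limitations

* Two conditions only; no paired/blocked designs or batch covariates.
* One test variant per engine (moderated t; NB LRT) — no quasi-likelihood
  F-tests, exact tests or robust/trended empirical Bayes.
* No quantile/upper-quartile/RLE normalization alternatives.
* Probe-level duplicate gene identifiers are rejected, not aggregated.
* No positional/codon-level analysis of ribosome footprints; the package
  operates on gene-level quantifications only.
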