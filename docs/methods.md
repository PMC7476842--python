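# Methods

## The model

`rpskit` predicts pathologic complete response (pCR) versus residual
disease (RD) after neoadjuvant chemotherapy from a pretreatment log2
expression profile. The method has two stages.

**Weight-profile construction.** For each gene *i*, a univariate logistic
regression `logit P(Y=1) = β₀ + β₁·xᵢ` is fit by maximum likelihood
(statsmodels), with Y = 1 for pCR. The Wald two-sided p-value of β₁ and the
sign of β₁ define a pair of mutually exclusive weight profiles:
`wᵢ⁺ = −log₁₀(pᵢ)·I(βᵢ > 0)` and `wᵢ⁻ = −log₁₀(pᵢ)·I(βᵢ < 0)`. Raw weights
are capped at `trim = 10` (i.e. p = 10⁻¹⁰ at base 10) to avoid extreme
values, then min–max rescaled into [0, 1]. The rescaling pools the raw
weights of *both* profiles, so the two sides share one scale and exact
zeros remain zero; per-profile rescaling would distort the balance between
the up- and down-sides of the final score. A TNBC-specific signature is
obtained by restricting the training cohort to ER−/PR−/Her2− samples
before fitting.

Fits on quasi-separated data have no finite maximum-likelihood estimate;
such genes (and any optimizer failure) are flagged `converged=False` and
receive zero weight, because their Wald p-values are meaningless. A
constant predictor is treated as β₁ = 0, p = 1. No multiple-testing
adjustment is applied — the weights use the raw p-value scale.

**Scoring.** Expression is median-centered per gene across the cohort
being scored. For one sample, the centered values are shifted by their
minimum (so cumulative sums stay non-negative; rank order is unchanged)
and sorted in descending order with a stable gene-id tie-break. Against a
weight profile *w* two cumulative curves are built,
`f(i) = Σ_{k≤i} eₖwₖ / Σ_{k≤g} eₖwₖ` and
`b(i) = Σ_{k≤i} eₖ(1−wₖ) / Σ_{k≤g} eₖ(1−wₖ)`,
and the raw statistic is the value of `f − b` at the index of largest
|f − b|. The sign-preserving convention (rather than the signed maximum)
lets depletion of the weighted genes at the top of the profile produce a
negative score, which the final difference requires. A null distribution
is generated by shuffling the expression values across gene labels
(`n_permutations = 1000`; the weights stay fixed) and the raw statistic is
z-transformed against the null mean and SD. This is done once with w⁺ and
once with w⁻, and `RPS = RPS⁺ − RPS⁻`. The z-transform was chosen as the
null normalization; an empirical-quantile transform would also be
defensible but is harder to difference stably at 1000 permutations.

Degenerate corner: uniform weights make f ≡ b for every permutation, so
the null has zero spread while the observed statistic is exactly the null
mean; this scores 0. Any other zero-spread null raises an error.

**Determinism.** Each sample's permutation stream is derived from the
master seed plus a hash of its own median-centered, gene-id-aligned
profile. Scores are therefore bit-reproducible, independent of cohort
column order and of gene row order, and identical for duplicated samples,
while still varying with the master seed.

## Preprocessing

- **Probe collapse:** for genes with several probesets, the probeset with
  the largest mean intensity across samples represents the gene; ties
  break to the lexicographically smaller probe id.
- **Quantile normalization:** every sample is mapped onto the across-sample
  mean of sorted value vectors; tied values receive the mean of the
  reference values at the tied ranks (limma convention). Idempotent on
  tie-free data.
- **Batch adjustment:** a parametric empirical-Bayes location/scale
  adjustment (ComBat-style): per-gene values are standardized against the
  batch-design fit, per-batch location and spread estimates are shrunk
  toward priors estimated across genes (normal prior for locations,
  inverse-gamma for spreads, solved by the standard iterative
  posterior-mean recursion), and the data are rebuilt on the original
  scale. `method='center_scale'` applies the same location/scale formula
  without shrinkage — it removes batch means exactly and preserves each
  gene's grand mean to machine precision, which makes it the testable
  reference; the EB path shrinks batch effects toward a common prior
  across genes, so when batch "effects" are indistinguishable from noise
  it deliberately adjusts less than the direct formula, and its grand-mean
  preservation is approximate rather than exact. Values are assumed
  already on a log2/RMA scale; nothing is re-logged. Whether quantile
  normalization is applied before or after merging cohorts is left to the
  caller — the CLI applies steps in the order flags are given.

## Comparator signatures

The generic Module score is `Σwᵢeᵢ / Σwᵢ` over the signature genes present
in the profile (missing genes are dropped and counted). The literal
denominator is the default; for signed-weight modules whose weight sum can
vanish, `abs_denominator=True` divides by `Σ|wᵢ|`. Composites built from
it: a 9-gene-style mean-expression score; a consensus score summing three
cohort-rescaled components (an immune module score, TOP2A and LAPTM4B
expression, each rescaled to median 0 / IQR 1 — quartiles use the midpoint
convention, the symmetric choice under which e.g. (1,2,3,4) has IQR 2); a
Her2-dependent combination (immune + stroma, plus a TOP2A module for
Her2-positive tumors); and a metagene difference (mitotic − ceramide).
Gene lists are always user-supplied TSVs; none are hard-coded, and
commercial assay algorithms are out of scope.

## Evaluation

- ROC curves sweep a "pCR if score > threshold" rule over every observed
  score; the AUC (trapezoidal, ties half) equals the Mann–Whitney
  concordance probability.
- Group difference: two-sided Wilcoxon rank-sum, exact for combined
  n ≤ 20 without ties, tie-corrected normal approximation otherwise.
- Tertile enrichment: samples split at the 1/3 and 2/3 score quantiles
  (boundary ties to the lower tertile); Pearson chi-square without
  continuity correction on the 2 × 3 table.
- Clinical integration: a random forest (500 trees, √p features per
  split) on score + age + stage + grade (stage/grade as ordered integers;
  unknown values exclude the sample, with a logged count). Per repeat,
  stratified 10-fold assignment; in each training split the majority
  class is subsampled to the minority class size, equalizing the class
  sample sizes the forest sees. Held-out class-1 probabilities are pooled
  across folds into one AUC per repeat (pooling is more stable than
  fold-averaging at TNBC-scale cohorts; a `fold_mean` switch is
  provided), and mean-decrease-in-impurity importances are averaged per
  repeat. Feature importances are compared by one-way ANOVA across
  features over repeats; per-dataset AUC vectors are compared by paired
  two-sided t-test.

## Enrichment

Gene sets (GMT; sets with fewer than 20 genes after intersection with the
ranked universe are dropped) are scored along the signature's genes ordered
descending by signed weight `w⁺ − w⁻`, zero-weight genes retained with a
stable gene-id tie-break so N is the signature's full universe. With hit
ranks r₁ < … < rₙ, cumulative hit counts gᵢ = i and gaps dᵢ = rᵢ₊₁ − rᵢ
under the sentinel rₙ₊₁ = N + 1, the enrichment score is
`ES = (Σgᵢdᵢ/(n·N) − 0.5)·2 ∈ [−1, 1]`. The sentinel is the only reading
under which hits concentrated at the top give ES → +1 (and at the bottom
→ −1), matching the interpretation that positive scores mean enrichment
among the up-regulated genes. Microenvironment association uses Spearman
correlation (average ranks) of sample scores against user-supplied immune
and stromal abundance estimates and a proliferation proxy (median-centered
MKI67 expression). Immune/stromal decomposition itself (e.g. ESTIMATE) is
consumed as a precomputed table, never recomputed.

## Synthetic cohorts

The generator emulates two-class Affymetrix-style data: per-gene baselines
~ N(7, 1.5) on the log2 scale, gaussian noise (`noise_sd = 1`), a planted
set of DE genes (default 200 of 2000) shifted by ±`effect_size`·noise_sd in
pCR samples — split 50/50 up/down so both weight profiles are exercised —
per-gene batch offsets ~ N(0, 0.5) across 2 batches, and 120 samples at a
30% pCR fraction, the response rate typical of neoadjuvant chemotherapy.
Stage and grade are drawn with their category log-odds tilted toward pCR
(`clinical_effect = 1`), reflecting that advanced-stage/grade TNBC tends to
respond more often; receptor statuses and age are independent of response.
Clinical covariates deliberately do not act on expression, so the score's
added value over clinical predictors is identifiable in CV comparisons.

What the generator does **not** emulate: probe-level artifacts
(cross-hybridization, spatial effects), count-based RNA-seq noise,
correlated gene modules, or platform differences. Passing tests therefore
demonstrate the machinery's correctness and calibration under the assumed
gaussian log2 model, not clinical performance on real cohorts.

## Problem sizes and defaults

The end-to-end experiments use 2000 genes, 240 samples (120 train / 120
held-out, split by simulated batch), 200 DE genes at a 1-SD shift, 1000
scoring permutations, and 10-fold CV repeated 20 times — sizes at which
the planted signal is recovered essentially perfectly (held-out AUC ≈ 1,
DE recall ≈ 100%) while a full run stays in the minutes range. Null
calibration uses 200 permuted profiles at 500 permutations each; the mean
score is expected near 0 with standard error ≈ 0.1, so calibration checks
on bands of ±0.15 carry Monte-Carlo noise of the same order.

## Known limitations

- Per-gene logistic fits ignore covariates and gene–gene correlation;
  penalized variants are out of scope.
- The permutation null treats genes as exchangeable within a sample;
  strong inter-gene correlation in real data makes the z-scores
  conservative or liberal depending on the signature.
- EB batch adjustment assumes roughly normal per-gene batch effects and
  complete data.
- The walking-sum ES has no built-in significance test; it is a
  descriptive annotation statistic.
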