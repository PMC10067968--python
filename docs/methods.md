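# Methods

## The model

A methylation age clock is a sparse linear predictor

    age = b0 + sum_j w_j * beta_j

of chronological age (years) from CpG beta values. We fit it by elastic-net
regression in the glmnet parameterisation

    (1/2n) * sum_i (age_i - b0 - x_i' b)^2
        + lambda * [ alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2 ]

with the mixing parameter fixed at alpha = 1/2 and the penalty strength
lambda selected by internal 10-fold cross-validation on the training
samples. Age is not transformed before regression. Predictors are
standardized internally and the stored coefficients are de-standardized
back to the beta scale; exactly-zero coefficients are dropped, so a fitted
clock usually keeps tens of CpGs out of a panel of hundreds or thousands.

### Assumptions

* Age-related methylation change is approximately linear in beta over the
  observed age range (0–48 years here). No juvenile log-linear adjustment
  is applied.
* The age signal at a CpG is at least partly shared across species and
  tissues; species- and tissue-specific *offsets* exist but are absorbed by
  the linear model only to the extent the training set spans them — hence
  the leave-one-species-out degradation.
* Missing probe values are missing at random; they are mean-imputed from
  the training samples (and a clock stores those means so the same
  imputation applies at prediction time).

## CpG pre-selection (leakage control)

Arrays measure far more CpGs than there are samples, so a panel of
age-correlated CpGs is chosen before fitting — using **training samples
only**. Per species × tissue stratum (blood, skin, and a combined
blood+skin stratum when a species has both tissues) each CpG receives the
Fisher correlation statistic z = atanh(r) * sqrt(n - 3) against age, with r
clamped to ±(1 − 1e−12) and computed over pairwise-complete observations.
Strata containing *any* test sample are removed; a stratum needs at least
`min_stratum_size` (default 5) members and a non-constant age vector to
contribute. Per CpG the median of the remaining per-stratum z values is
taken (a robust meta-analysis across strata with very different sample
sizes), and CpGs are ranked by |median z|, ties broken by CpG id. Ranking
by absolute value rather than per-direction quotas is the minimal reading
of "most age-correlated"; a per-direction split is available downstream in
the EWAS top-set logic.

The default panel size is k = 4000, matching the ~4k-of-37k share of a
full mammalian array. The test suite and the acceptance script run on
4000-CpG synthetic panels and use k = 100 (a comparable few-percent share)
— this keeps full leave-one-out loops at roughly 20–30 s per cohort on one
CPU while leaving panel selection a genuinely active step.

## Cross-validation schemes

* **LOOCV** — one fold per sample.
* **LOAOCV** — one fold per animal; an animal's blood and skin samples are
  held out together, removing the dependence created by paired samples.
* **LOSOCV** — one fold per species; measures extrapolation to species
  absent from training (requires ≥ 2 species).

Each fold reruns pre-selection with its own test set excluded, fits the
clock on the training samples, and predicts the held-out samples; thus no
test information can reach either the panel or the coefficients (asserted
bit-exactly in the tests). Folds whose training data cannot support
pre-selection are skipped with a warning and counted, never silently
dropped. Accuracy is Pearson r between predicted and true age plus the
**median** absolute error (MAE, years); the mean absolute error is also
reported separately to avoid ambiguity. Per-species and per-tissue metrics
are emitted only for groups with ≥ 3 out-of-fold predictions.

## EWAS and enrichment

Within a stratum every CpG is tested for Pearson correlation with age over
pairwise-complete samples; the two-sided p value uses the t approximation
t = r * sqrt((n-2)/(1-r^2)) on n − 2 degrees of freedom (standard for
correlation tests; a permutation option exists for very small strata via
the same public statistics). No multiple-testing correction is applied to
selection — significance is nominal p < 0.005, and an optional
Benjamini–Hochberg q column is informational only. Top sets take up to 500
CpGs per direction of association, ordered by (p, CpG id). Overlaps across
strata are exact Venn partitions.

Enrichment statistics:

* **Gene regions**: two-sided Fisher exact test per region class on the
  2×2 (in top set × in class) table over the CpG background; odds ratios
  get a Haldane–Anscombe 0.5 correction when a cell is zero (the p value
  stays exact; the uncorrected OR is also reported).
* **CpG islands**: Welch two-sample t test comparing the Fisher-z
  distributions of island vs non-island CpGs, with box-plot summaries.
* **Chromatin states**: one-sided (upper-tail) hypergeometric test per
  state; the background is restricted to CpGs alignable in *all* analysed
  species, mirroring how cross-species probe sets must be compared.
* **Gene sets** (GMT input): CpGs map to genes with |distance to TSS| ≤ 50
  kb; the gene universe is derived from the CpG background through the same
  flank rule, so background restrictions propagate to the gene level.
  Results are filtered at p < 1e−5 and overlap ≥ 3 genes.

One-sided tests for state/gene-set enrichment match their "enrichment"
framing; the region analysis is two-sided because depletion is equally
interesting there.

## Synthetic cohorts

`simulate_dataset` draws a multi-species, multi-tissue cohort with known
ground truth. Per sample i and CpG j:

    mu_ij = expit(b0_j + s_j * age_i + u_{j,sp(i)} + v_{j,t(i)})
    beta_ij ~ Beta(mu_ij * precision, (1 - mu_ij) * precision)

* Baselines b0_j follow a bimodal mixture (modes near beta 0.1 and 0.9
  plus a uniform middle component), the typical array beta distribution.
* A chosen minority of CpGs get age slopes s_j of magnitude
  `slope_scale × U(0.5, 1.5)` logit units/year, half positive and half
  negative; all other slopes are zero.
* Per-CpG species offsets u ~ N(0, species_sd) and a skin-vs-blood offset
  v ~ N(0, tissue_sd) create the between-species / between-tissue structure
  that makes LOSOCV genuinely harder than LOOCV.
* Ages are uniform over 0–48 years per animal; a configurable fraction of
  animals contributes both a blood and a skin sample under one animal id.
* Annotation labels (gene, region, island status, chromatin state) are
  random and independent of the age signal, so enrichment analyses are
  *null* on synthetic data — they exercise correctness and calibration, not
  biological signal.

Defaults describe the reference conditions used throughout the tests and
the acceptance script: 3 species × 30 animals, two-thirds of animals with
both tissues (exactly 150 samples), 4000 CpGs with 400 age-related,
slope_scale 0.05 logit/yr, species_sd = tissue_sd = 0.5, precision 60.
Everything is deterministic given the seed.

What passing on synthetic data does **not** show: robustness to probe
cross-hybridisation, batch effects, SNP-confounded probes, non-uniform age
distributions, or age-correlated annotation structure — none of which the
generator emulates.

## Numerical choices

* Correlations: r clamped to ±(1 − 1e−12) before atanh; per-stratum
  computation needs ≥ 4 complete pairs and non-constant inputs; variances
  below 1e−18 are treated as zero (cancellation guard).
* Elastic net: lambda path of 50 values (30 in the large leave-one-out
  loops) spanning a factor of `lambda_min_ratio` = 0.01 below the
  data-driven maximum — the glmnet convention when samples < predictors;
  coordinate-descent tolerance 1e−3. The CV-minimising lambda is the
  default ("min"); the "one-SE" rule is available. Internal CV folds are
  stratified by age quantile (seeded), falling back to plain shuffled
  folds when bins are too small.
* Determinism: inputs are copied into a canonical C-contiguous layout
  before fitting so that identical values give bit-identical models
  regardless of how the caller sliced them; predictions accumulate
  weighted CpGs in sorted order; all randomness flows from explicit seeds
  (the pipeline derives per-stage seeds from one global seed via
  `numpy.random.SeedSequence`).
* Serialization: floats are written with `repr` (17 significant digits),
  so clock write → read round trips are bit-identical; CSV readers use
  round-trip float parsing for the same reason.
* Degenerate inputs: constant ages, single-species LOSOCV, empty strata,
  beta values outside [0, 1], zero-weight clock entries and train/test
  overlaps all raise typed errors rather than propagating NaNs. An
  all-missing CpG in a training set is imputed at 0.5 and flagged.

## Known limitations

* The t-approximation p values are slightly anti-conservative for very
  small strata (n ≲ 10); use larger `min_stratum_size` or permutation
  checks there.
* With strong synthetic signal and the CV-minimising lambda the final
  clock can retain most of a small panel; sparsity comparable to real
  clocks (tens of CpGs) emerges with larger panels and noisier signal.
* The gene-set engine is a generic hypergeometric test on a flank-derived
  gene universe; it does not reproduce regulatory-domain models of
  web-based enrichment services.
* Clocks are not recalibrated against known-age field data; predictions
  for truly novel species inherit the LOSOCV-scale error.
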