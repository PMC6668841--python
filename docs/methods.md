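# Methods

## Overview

`vistl` implements an image-based framework for predicting in-hospital
mortality from the first 48 hours of an admission. Sparse, timestamped
clinical observations are converted into a normalized 2D "visual timeline"
(variables on the vertical axis, hours on the horizontal axis, pixel
intensity = normalized value), and a convolutional network with a recurrent
layer (CNN-RL) classifies the image. Maximum MEWS and SOFA scores over the
same 48 hours serve as bedside comparators, AUCs are compared with paired
DeLong tests, and Grad-CAM heatmaps localize the image regions driving each
prediction. Because inpatient EHR extracts of this kind cannot be shared, a
calibrated synthetic-cohort generator stands in for the data; everything
downstream of the generator treats its output exactly as it would treat a
real extract (long-format observation tables keyed by admission id).

## Timeline encoding

1. **Hourly blocking with LOCF.** Hour bins are 0-based and half-open,
   `[h, h+1)`. A cell holds the latest observation of its variable in the
   bin; within a bin the later timestamp wins and exact timestamp ties
   resolve to input order, making the encoding deterministic. Cells with no
   in-bin observation carry the most recent earlier value forward.
2. **Static rows.** Demographics, comorbidity flags and admission location
   are rendered as constant rows across all 48 columns (location as a
   one-hot block).
3. **Imputation.** Cells still missing after LOCF are filled with
   location-specific medians fitted on the *training split only*, falling
   back to the global median, then to the plausible-range midpoint; binary
   variables impute 0 (absence). The fitted statistics carry the id set
   they were fitted on, and the training loop asserts that no validation
   admission ever enters a batch.
4. **Normalization.** Two schemes. *min-max*: `(x - low) / (high - low)`
   clipped to [0, 1], where `low`/`high` are the training 1st/99th
   percentiles clipped to the plausible range (percentiles rather than raw
   extremes so a single outlier cannot compress the whole row; raw min/max
   is available via `percentile_bounds=False`). *custom*: direction-aware,
   so 0 is clinically normal and 1 abnormal — higher-abnormal variables as
   min-max, lower-abnormal inverted, and both-tails variables mapped by
   distance from the training mean scaled by the larger one-sided span
   (`min(|x - mean| / max(mean-low, high-mean), 1)`). The magnitude
   (unsigned) reading was chosen for the both-tails case; a signed variant
   would double the dynamic range but break the "0 = normal" convention.
   Binary rows pass through as absence/presence in both schemes.
5. **Row ordering.** *standard* keeps the catalogue's grouped order;
   *within-group* and *across-group* cluster variables by Pearson
   correlation of their pixel rows pooled over training (admission x hour)
   cells, complete-linkage on distance `1 - r`, displayed in dendrogram
   leaf order (within each group block, or globally). Zero-variance rows
   are assigned zero correlation to all others.

PNG export writes 8-bit grayscale, `byte = round(255 * value)`, row 0 at
top and hour 0 at left; black = low/absent, white = high/present.

## Bedside comparators

MEWS (five components, each 0-3: systolic blood pressure, heart rate,
respiratory rate, temperature, AVPU consciousness; total 0-14) and SOFA
(six organ systems, each 0-4; total 0-24) are computed on the *imputed
native-unit* hourly grid — the same blocking/imputation stages as the image
encoder, before any normalization — and summarized as the maximum over the
48 hours. Banding tables are shipped as CSV data (`data/mews_bands.csv`,
`data/sofa_bands.csv`) with half-open `[previous_upper, upper)` intervals,
so variant site bands can be swapped without touching code. Two
simplifications: the SOFA cardiovascular component maps any vasopressor use
to 3 points (the published table grades by dose, which the data model does
not carry), and the renal component uses creatinine only by default, since
a 24-hour urine volume is undefined hour-by-hour (an `include_urine` flag
scales the hourly rate to a 24-h volume from hour 24 on). Scores are
computed hourly and then maximized; a windowed-worst variant was considered
and rejected as it only lowers temporal resolution.

## Models

Three architectures operate on V x 48 images (NumPy implementation with
explicit backpropagation; conv = 3x3 same-padding via im2col + GEMM; all
layer gradients are verified against finite differences in the test suite):

* **standard_cnn** — conv blocks with 2x2 max pooling and a dense head;
  the pooling discards fine temporal ordering.
* **rnn** — a GRU over the 48 hourly column vectors.
* **cnn_rl** — conv blocks pooling *only the variable axis* (2x1), so all
  48 time steps survive to a GRU over the per-time-step feature vectors.
  The GRU head feeds the mean of its hidden states to the output (stabler
  than last-state across seeds; still order-sensitive). This is the
  framework's primary model: convolution finds local patterns, the
  recurrent layer reads their ordering.

Defaults (exposed in `ModelConfig`): filters (8, 16), kernel 3, GRU width
48, dropout 0.2, Adam at 1e-3, batch 128, up to 10 epochs with early
stopping (patience 3) on tuning-split AUC, inverse-prevalence class weights
for the ~2.5% positive rate. Sizes are deliberately small: each model
trains in tens of seconds on one CPU at n = 8,000 while preserving the
architectural contrast under study. Splits follow the study protocol: 70%
derivation / 30% independent validation, derivation split 80/20 into
training/tuning (smaller set rounded down), all at admission level.

## Evaluation

AUC is the Mann-Whitney statistic with half-credit ties. Confidence
intervals and paired model comparisons use DeLong placement values with a
normal approximation; DeLong was chosen as the standard test for correlated
AUCs on a shared validation set, and is checked in the tests against a
stratified bootstrap (CIs) and a 10,000-rep score-swap permutation test
(p-values). AUPR is step-wise average precision (point estimate only). The
single-pixel robustness experiment zeroes one uniformly random pixel per
validation image and re-computes AUC.

## Interpretation

Grad-CAM: channel weights are the spatial means of the death-logit gradient
at the final convolutional layer's (post-ReLU) feature maps — for cnn_rl
the gradient flows back through the recurrent head — and the rectified
weighted sum is bilinearly upsampled to V x 48 and scaled to max 1.
Overlays blend the grayscale timeline with a blue-to-red palette using the
attention itself as blend weight. The differential image is
`mean(alive) - mean(died)` with an |.|/max display version (white = largest
class difference).

A caveat established empirically here: with shallow conv stacks (two
blocks), channel-pooled Grad-CAM tracks local image contrast more than
class evidence, because weight-shared filters are not row-specific and the
spatial mean of the gradient discards the head's position information. The
attention-localization analysis therefore uses a three-block cnn_rl
(`conv_filters=(8, 16, 32)`), whose final-layer channels have larger
receptive fields and localize far better, and evaluates attention on
*deceased* patients, where the evidence is present rather than absent. The
analysis contrasts contiguous variable-group areas (nurse examinations,
interventions, diagnostic tests) rather than isolated single rows, matching
the area-level granularity the upsampled map can resolve.

## Synthetic cohort generator

The generator's role is to emulate the *study conditions*, not disease
physiology. Per admission: location ~ Categorical(0.308 ward, 0.413 ED,
0.058 ICU, 0.221 other), age truncated-normal (mean 54.4, sd 19 on
[18, 100]), sex Bernoulli(0.5675), race and age-linked comorbidity flags. A
scalar latent severity follows a discrete mean-reverting process around a
location baseline (ward 1.0, ED 1.1, ICU 2.25, other 0.0; reversion 0.25,
innovation sd 0.15, initial sd 0.6) plus a per-admission linear trend
(slope sd 0.03/h), giving each patient a drifting 48-hour acuity path.
Death is Bernoulli with logit
`-7.745 + 1.7 * max48(severity) + 0.034 * (age - 55) - 0.48 * female`;
length of stay is outcome-conditional lognormal (medians 9 and 5 days)
floored at two days, matching the design that only admissions of >= 48 h
enter and deaths occur after hour 48.

Observations are emitted per variable from a Poisson process (vitals
guaranteed at least one observation in hour [0, 1)); continuous values are
`normal_value + link * relu(severity) + noise`, clipped to the plausible
range; binary values are Bernoulli with logit linear in severity;
consciousness is an ordinal AVPU level and a GCS band driven by severity
thresholds. Centering at a clinically normal resting value (rather than the
plausible-range midpoint) keeps healthy synthetic patients scoring ~0 on
MEWS/SOFA.

Two calibrations were performed once, by simulation, and frozen as
defaults:

1. **Admission-level marginals** (intercept, demographic coefficients,
   baselines, LOS parameters) reproduce the reference cohort table at
   large n: ~2.5% mortality; ICU 25% of deaths vs 5% of survivors; mean age
   63 vs 55; female 47% vs 57%; median LOS 9 days among deaths. The latent
   heterogeneity was set so that the oracle AUC of the true outcome logit
   is ~0.90 — the discrimination level the framework's best model should be
   able to approach.
2. **Relative information content.** The channels the bedside scores read
   (MEWS vitals, SOFA organ labs, AVPU/GCS) carry weak severity links and
   sparse sampling relative to their banding thresholds, while channels
   only the image models see (Morse/Braden nurse scores, BUN, lactate,
   FiO2, urine output, medication/intervention/diagnostic-test flags, and
   the demographic rows, which enter the outcome logit directly) are
   high-signal. This is what makes banded 5-7-channel max-scores genuinely
   less informed than the full image, reproducing the study's relative
   ordering (SOFA < MEWS < CNNs) rather than its absolute AUCs. A handful
   of channels (sodium, glucose, pain score, insulin, race, comorbidities)
   are pure-noise by design and serve as negative controls for the
   interpretability analyses.

What the generator does **not** emulate: inter-variable correlation beyond
the shared scalar latent, multi-morbidity structure, ward transfers
(location stratification therefore uses admission location), measurement
artifacts, or documentation bursts. Passing tests demonstrate that the
pipeline recovers structure a real cohort of this shape could carry — not
that the models would reach the same AUCs on real EHR data.

## Problem sizes used by the packaged analyses

The acceptance script generates one n = 50,000 cohort (the calibration
check). The discrimination-ordering analysis uses five seeded n = 8,000
cohorts with up to 8 training epochs per model; the attention-localization
analysis five seeded n = 4,000 cohorts with the three-block cnn_rl. These
sizes keep every analysis reproducible in minutes on a single CPU while
leaving the measured contrasts well clear of their decision thresholds.

## Known limitations

* The NumPy training loop is single-threaded BLAS-bound; it is meant for
  desk-scale cohorts (10^3-10^4 admissions), not production training.
* DeLong p-values use a normal approximation; at very low event counts the
  evaluation layer falls back to the widest CI with a warning.
* Grad-CAM at two-block depth is contrast-dominated (see above); overlay
  galleries are rendered for the model actually trained, so interpret
  shallow-model heatmaps with care.
* The full-preset catalogue pads to 156 rows with generic numbered
  channels; their clinical names are placeholders, preserving only the
  matrix geometry.
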