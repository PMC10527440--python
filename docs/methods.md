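# Methods

This note records the model, the numerical conventions, the open design
choices and their rationale, and what the synthetic benchmark does and does
not establish.

## Labelling and exclusion

Valence and arousal self-reports (1–9) map to labels via strict
inequalities: stress iff valence < 3 and arousal > 5; calm iff
4 < valence < 6 and arousal < 4; everything else is unlabeled and dropped.
The gap between the two regions is intentional — ratings at the printed
boundaries (valence exactly 3, arousal exactly 5) belong to neither class.
A subject is retained only with at least one trial of each class, since the
selection statistics are within-subject contrasts.

## Hjorth descriptors

Activity, mobility and complexity are computed with the first-order forward
difference as the derivative operator and **no sampling-rate scaling**:
mobility and complexity are variance ratios in which an fs factor would
cancel, and activity never involves one, so values are comparable across
sampling rates (mobility is then in radians per sample; for a slow sine it
approaches 2πf/fs). Variances use the unbiased N−1 denominator throughout
the Hjorth/selection path, matching the covariance convention of the
channel–channel correlation.

Z-scoring is per subject and per (channel, descriptor) column across that
subject's labeled trials with **both classes pooled** — selection is
per-subject and the class contrast must survive normalization; pooling is
also what lets the point-biserial relevance see the between-class mean
shift. `zscore(..., per_class=True)` is provided for sensitivity analysis.
Normalization happens once, before all correlation computations. A constant
column raises rather than silently producing zeros, because every
downstream correlation is undefined there.

## Selection

The channel–channel (redundancy) correlation aggregates the three
descriptors in a single ratio — sum of covariances over sum of
standard-deviation products — computed within each class across its trials
and pooled over classes by an elementwise mean. It is symmetric with a unit
diagonal and reduces to the ordinary Pearson correlation when one
descriptor dominates.

The channel–class (relevance) score defaults to the point-biserial
correlation of each descriptor with the binary class indicator, averaged in
absolute value over the three descriptors. Absolute values make
anti-correlated channels count as relevant, which is the appropriate
reading for a selection criterion. An alternative "paired" mode rank-pairs
the stress and calm trials (truncated to the smaller class) and correlates
them per descriptor; it is kept as a documented interpretation variant, not
the default, because its pairing is undefined for unequal class sizes and
its value is not bounded like a correlation of independent samples.

Two merit functions score a k-channel subset with mean relevance `r_cf` and
mean absolute pooled pair correlation `r_ff` (defined as 0 for k = 1):

- `literal`: `k·r_cf / (k + k(k+1)·k·r_ff)` — one printed variant of the
  correlation-feature-selection merit. Algebraically, this expression never
  exceeds the best single-channel relevance for k ≥ 2 (it equals `r_cf` at
  `r_ff = 0` and decreases from there), so a forward search under it always
  stops after one channel.
- `cfs` (search default): the classical merit
  `k·r_cf / sqrt(k + k(k−1)·r_ff)`, which rewards adding weakly redundant,
  relevant channels and is the form the literal variant descends from.

Because a method whose whole point is cross-subject occurrence counting
needs multi-channel per-subject sets, the greedy search defaults to `cfs`;
`literal` remains selectable end to end and every report records the mode
used. `r_ff` uses the **absolute** pooled pair correlation: redundancy is a
magnitude, and this also keeps the literal denominator positive.

The per-subject search is greedy best-first with a patience of zero: start
empty, add the channel maximizing the merit of the augmented subset, stop
at the first non-improvement. Ties break toward higher relevance, then
lexicographically smaller channel name, making the search deterministic.
A `topk` strategy (k highest relevance scores) is the simple alternative.

Cross-subject aggregation counts, per channel, the number of subjects whose
set contains it; channels with count ≥ `f_thr` are ranked by descending
count (ties: descending mean relevance, then name) and truncated to
`n_max`. The occurrence threshold is not dictated by the method itself;
the default `f_thr = ceil(n_subjects/2)` ("selected for at least half the
subjects") with `n_max = 8` mirrors the common practice of reporting an
8-channel montage. Both are parameters everywhere.

Selection operates on whole trials by default (the trial is the sampling
unit of all covariances); `selection_unit: segment` in the pipeline config
switches to 480-sample segments as pseudo-trials for comparison.

## Features

Per 480-sample segment and channel, 20 features in a fixed column order.
Conventions that matter:

- Kurtosis and skewness are population (1/T) standardized moments with no
  excess correction (Gaussian kurtosis ≈ 3). This deliberately differs from
  the N−1 convention of the correlation machinery; each formula follows its
  own standard definition.
- Welch PSD: 128-sample Hamming windows, 50% overlap (three averages per
  segment, 1 Hz resolution — enough to resolve the 4 Hz band edge),
  configurable via `nperseg`. Band powers integrate the PSD (trapezoid)
  over theta 4–8, low alpha 8–12, high alpha 12–15, low beta 15–20 and
  high beta 20–30 Hz; relative powers divide by total 4–45 Hz power — the
  full passband of the (pre-filtered) data, the natural "total" for data
  whose content outside 4–45 Hz was removed upstream — and multiply by 100.
  The five bands tile 4–30 Hz, so their sum is ≤ 100.
- Wavelet energies: squared-coefficient sums of the D1…D6 detail levels of
  a 6-level db4 decomposition, symmetric boundary extension. The
  approximation band is excluded because at 128 Hz it lies below 1 Hz,
  which the 4–45 Hz band-pass already removed; `coeff_set="d2_d6_a6"`
  swaps D1 for the approximation instead. Symmetric extension is the
  reproducible default; `mode="periodization"` gives exact Parseval energy
  conservation when the length divides by 2^level.
- Spectral entropy: Shannon entropy (natural log by default, base 2
  optionally) of the 4–45 Hz Welch spectrum normalized to unit sum.
- Katz fractal dimension: `log10(n) / (log10(d/L) + log10(n))` with L the
  curve length, d the maximal excursion from the first sample and
  n = N − 1 steps; 1 for a monotone ramp, > 1 for irregular signals.

The three Hjorth columns delegate to the Hjorth module — a single source of
truth, verified by test.

## Classification

Stratified seeded 10-fold cross-validation within each subject;
stratification is used because per-subject class counts under the labelling
rule are small and imbalanced. Metrics come from the confusion counts
pooled across test folds (not fold-macro averages), with stress as the
positive class; a zero-denominator metric is reported as NaN, never as 0.
Features are standardized inside each fold using training-fold statistics
only (a per-fold pipeline), since RBF-SVM and KNN are otherwise dominated
by the large-scale activity/energy columns; `scale=False` restores the
unstandardized reading. SVM gamma uses the `scale` heuristic
(1 / (n_features · var)); "regularized LDA with no shrinkage" is plain LDA
with the eigen solver — note its within-class scatter must be nonsingular,
so the feature count (20 × channels) must stay below the per-subject
segment count. The channel sweep re-runs the CV on the top-s ranked
channels for s in {1, 5, 8, 9, 15, 19, 32} by default, each channel
contributing its full 20 features.

## Synthetic data

Backgrounds are synthesized in the frequency domain: complex-Gaussian
spectral coefficients under a 1/f amplitude envelope restricted to
4–45 Hz, inverse-transformed and scaled to unit expected RMS. Random
(Rayleigh) coefficient amplitudes — not fixed ones — are essential so that
per-trial power fluctuates and across-trial variances are nondegenerate.
Inter-channel correlation is zero by default; a `mixing` parameter blends
in a shared component to emulate volume conduction for harder regimes.

Stress trials of the planted channels receive, per `effect_kind`:

- `bandpower_shift` — an added 15–30 Hz narrowband component with RMS =
  `effect` × background RMS (raising activity and mobility);
- `mobility_shift` — an envelope tilt `f^(0.15·effect)` that moves the
  spectral centroid, hence the discrete mobility, upward;
- `mixed` — both.

Defaults (32 channels with standard 10–20 names, 40 trials of 60 s at
128 Hz, balanced classes) mirror the shape of the public affect dataset the
method targets. What the generator does **not** emulate: eye blinks,
drifts, evoked responses, inter-subject variability of effect topography,
or any physiological channel covariance. Passing the planted-recovery
benchmark therefore shows the statistical machinery recovers a known
class-dependent Hjorth contrast under realistic band-limited noise — it
does not certify performance on real EEG, where effects are weaker and
channel backgrounds are correlated.

## Benchmark problem sizes

The recovery benchmark runs 10 subjects × 16 channels × 40 trials with
8-s trials: trial length enters the Hjorth statistics only through the
variance of the descriptor estimates, and 1024 samples per trial already
estimates them stably, so short trials are used for the repeated-simulation
studies while the single-run tests exercise the full 60-s shape. The
classifier demonstrations use 15-s trials cut into four 480-sample
segments for the same reason.

## Error handling

Contract violations (shapes, ranges, unknown names) raise `ValidationError`
(CLI exit 2); unreadable/missing files surface as I/O errors (exit 3);
numerical degeneracies — zero-variance signals, constant feature columns,
singular correlation denominators — raise `DegenerateSignalError` (exit 4)
naming the offending trial/channel rather than propagating silent zeros.

## Known limitations

- The EDF writer is minimal (16-bit, single physical dimension in
  microvolts, continuous records); it targets fixtures and interchange,
  not clinical archiving.
- The literal merit variant is kept for faithfulness but is degenerate as
  a search objective (see above).
- The paired channel–class mode is an interpretation variant with no
  canonical definition for unequal class sizes.
- No artifact rejection: inputs are assumed preprocessed (band-passed,
  ocular artifacts removed).
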