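# Methods

## Problem and scope

`tremorkit` classifies parkinsonian rest-tremor severity (0 = none,
1 = mild, 2 = strong) from 30-second windows of 6-channel wrist/ankle IMU
data (3-axis accelerometer in m/s², 3-axis gyroscope in deg/s, 50 Hz),
labelled by a clinician at 3-minute intervals during free-living activity.
Each window is labelled with the score entered at its end; windows and
labels are always limb-matched, and windows from all limbs and subjects are
pooled into one cross-patient sample set. The package covers the full chain
— synthetic data generation, ingestion and windowing, band-specific
preprocessing, feature extraction and selection, class rebalancing,
SVM classification and dual evaluation — as a library with a thin CLI.

## Synthetic session generator

No public dataset of clinician-scored free-living IMU sessions exists, so
the generator produces sessions with the statistical structure the
analysis assumes. What it emulates:

* **Severity dynamics.** Severity is piecewise constant in bouts. Bout
  durations are uniform on [2.5, 7.5] min (mean 5 min, so states persist
  across neighbouring 3-min scoring intervals); each bout's severity is
  drawn independently from the stationary probabilities
  (0.915, 0.075, 0.01) — equivalently a Markov chain whose transition rows
  all equal the stationary vector. This makes the long-run label marginal
  match the target exactly and converge quickly (±0.01 over a 10⁶ s
  horizon). A "sticky" chain with state-dependent dwell would either break
  exact stationarity or give the majority state hour-long dwells and far
  slower convergence; since no dwell-time statistics are available to
  calibrate against, the memoryless choice is the defensible one.
* **Tremor.** Per bout, an amplitude-modulated sinusoid: carrier drawn
  uniformly in 4–7 Hz once per bout, envelope = |low-pass-filtered
  Gaussian noise| (2nd-order Butterworth, 0.25 Hz cutoff, so the envelope
  varies below ~0.5 Hz), normalized to unit RMS. RMS amplitude per severity
  defaults to (0, 0.5, 2.0) m/s² — zero for severity 0 by definition, and
  two values chosen so classes overlap with voluntary movement yet remain
  separable; no clinical amplitude statistics are available to estimate
  them. The tremor waveform is projected onto a random fixed 3-D unit
  direction per bout (accelerometer), and an independent direction for the
  gyroscope, scaled by 25 (deg/s)/(m/s²).
* **Voluntary movement.** Gaussian noise band-passed to 0.5–3 Hz
  (zero-phase, 8th-order), standardized to unit variance and scaled to
  0.6 m/s² RMS, with its own fixed random direction per session.
* **Sensors.** White noise (default SD 0.05 m/s² per accel channel, scaled
  for the gyroscope) and a constant 9.81 m/s² gravity offset on the accel
  z-axis. Orientation dynamics are not modelled: the analysis high-pass
  removes the gravity term, so only its DC character matters.
* **Scoring.** One score per 180 s (the first, at t = 0, has no preceding
  data and is dropped at windowing); the label is the modal severity of
  the preceding 30 s; with probability 0.02 the entry is "no data"
  (observation gaps such as personal privacy time).

What it does **not** emulate: biomechanics (gait, posture transitions),
dyskinesia or bradykinesia signatures, inter-patient frequency profiles,
sensor drift, or label noise by the scoring clinician. Consequently,
passing end-to-end tests shows the pipeline recovers the severity signal
it was designed for under controlled conditions — not that clinical
accuracy of any particular level would be achieved on real patients.

## Preprocessing

* Tremor chain: 10th-order Butterworth high-pass, 3.5 Hz cutoff, applied
  single-pass; then 10th-order Butterworth low-pass, 7.5 Hz, applied
  forward–backward (zero-phase). The high-pass therefore shifts phase;
  band-separation checks compare at the best alignment lag.
* Voluntary chain: 10th-order Butterworth band-pass, 0.5–3 Hz, single-pass.
* All designs are realized as cascaded second-order sections; an order-10
  direct-form realization is numerically unstable.
* Edge handling: signals are reflect-padded by one settle length before
  single-pass filtering and trimmed afterwards. The settle length is where
  the impulse response falls below 10⁻³ of its peak (≈ 8 s for the
  band-pass at 50 Hz); windows shorter than three settle lengths are
  rejected rather than padded, since padding distorts spectral features.
  The 10⁻³ criterion keeps the padding shorter than the 30 s window while
  suppressing boundary transients well below signal scale; the impulse
  responses themselves decay below 10⁻⁶ of peak well within a 60 s horizon
  (verified by test).
* Accelerometer channels are combined into the vector magnitude after
  band filtering (tremor is oscillatory, not directional); gyroscope axes
  are kept separate, as rotational tremor can be axis-specific.
* Wavelet tremor energy: continuous wavelet transform with an analytic
  Morlet wavelet (`cmor1.5-1.0`), frequency grid 3.5–7.5 Hz in 0.1 Hz
  steps, applied to the tremor-band accelerometer magnitude. The per-time
  energy is the trapezoidal integral of |X(f, t)| over the grid —
  magnitudes, not complex coefficients, since integrating complex values
  cancels phase across scales.

This yields 9 derived series per window (tremor-band accel magnitude,
3 tremor-band gyro axes, voluntary-band accel magnitude, 3 voluntary-band
gyro axes, wavelet tremor energy) in a fixed order.

## Feature space

10 features per derived series (90 total), named `<series>__<feature>`:

| feature | definition / conventions |
|---|---|
| mean, std | SD uses the n−1 denominator |
| iqr | linear-interpolation quantiles |
| cv | SD/\|mean\|; defined as 0 when \|mean\| < 10⁻¹² (band-filtered series are near zero-mean; SD and RMS carry the scale) |
| rms | root-mean-square |
| dom_freq | argmax of the Welch PSD (8 segments, 50 % overlap, Hann; segment length ⌊2n/9⌋ so 8 half-overlapping segments tile the window) |
| band_ratio | PSD mass in 3.5–7.5 Hz over total |
| spec_entropy | −Σ pᵢ log₂ pᵢ / log₂ m over normalized PSD bins (0 for a pure tone bin, →1 for white noise) |
| apen | ApEn(m = 2, r = 0.2·SD), Chebyshev distance, self-matches included; 0 for constant series |
| ac_zero_lag | lag (s) of the first non-positive value of the biased autocorrelation; 0 for constant series |

Zero-power spectra map to (dom_freq, band_ratio, spec_entropy) = (0, 0, 0).
ApEn is the O(n²) definition, compiled with numba for throughput; the test
suite holds an independent pure-Python double-loop oracle that must agree
exactly.

## Selection, rebalancing, model

* **MI ranking** uses the k-nearest-neighbour mutual-information estimator
  for a continuous feature against the discrete label (k = 3), averaged
  over 5 estimator seeds (the estimator jitters values to break ties),
  computed on the *full* pre-resampling matrix; ties in the ranking break
  by fixed feature-name order. The top 30 features are retained.
* **Rebalancing** to 300 rows per class: uniform random undersampling for
  classes above target (complement retained as the discarded pool), SMOTE
  for classes below (k = 5 neighbours, capped at class size − 1).
  Neighbours are found in z-scored selected-feature space; interpolation
  is applied to raw coordinates, so synthetic rows lie exactly on the
  parent segment. Parent pairs are stored per synthetic row.
* **Classifier**: SVC with RBF kernel, C = 1, gamma = 'scale'
  (1/(d·Var)), one-vs-one multiclass, after z-scoring with training-set
  statistics. No hyperparameter search — the pipeline's purpose is the
  end-to-end methodology, and the synthetic benchmark is not a tuning
  target. The 75/25 split is plain random (not stratified): the balanced
  dataset makes stratification nearly irrelevant.
* **Sensitivity** is binary any-tremor detection: P(predicted ≥ 1 | true ≥ 1).
  Adjacent/non-adjacent misclassification rates are the fractions of all
  samples with |true − predicted| = 1 and = 2 respectively.
* **PCA embedding** (2 components) is fitted once on the initial
  (pre-resampling) selected-feature matrix, standardized with the same
  statistics, and the identical transformation is applied to the resampled
  dataset so synthetic rows can be displayed in the same coordinates.

## Problem sizes

The default benchmark simulates 24 subjects × 1 limb × 2 h 48 min
(≈ 1,300 windows), mirroring the number of patients such a study enrols
while keeping a single-core run in minutes. Desk-scale checks (selection
robustness across 10 generator seeds, the noise-degradation trend across
5 seeds × 2 noise levels) use 3-session cohorts of 1 h with boosted
severity probabilities (0.5, 0.3, 0.2) and shorter bouts so every class is
populated at small n; these probabilities alter only class frequency, not
the signal model. The noise trend compares sensor-noise SDs 0.05 vs 4.0
m/s² — the high level is chosen on the order of the largest tremor
amplitude so degradation is identifiable above small-sample variance.

## Known limitations

* The 90-feature catalog reconstructs the three stated feature classes at
  the documented 9 × 10 layout; an exact historical feature list for this
  kind of analysis is not available, so other catalogs of the same classes
  are possible.
* Whether SMOTE should run before or after feature selection, and in
  scaled or raw space, is an open methodological choice; here selection
  uses the full dataset and SMOTE runs afterwards in selected-feature
  space (neighbours scaled, interpolation raw), and both choices are
  explicit in the API.
* Synthetic benchmark accuracies are near-perfect by construction and must
  not be read as expected clinical performance; clinical headline numbers
  require the (undeposited) patient recordings.
* No k-fold cross-validation, per-limb models, bradykinesia features, or
  streaming inference.
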