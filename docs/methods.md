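# Methods

## Problem and pipeline

`moodscreen` implements an instrumented screening method for childhood
internalizing disorders (anxiety, depression, trauma-related
conditions).  During a brief standardized fear-induction task a child
wears a belt-mounted IMU (3-axis accelerometer + 3-axis gyroscope,
nominally 300 Hz).  The task has three phases anchored on the startle
moment: Potential Threat [−23 s, −3 s), Startle [−3 s, +3 s) and
Response Modulation [+3 s, +23 s), half-open on the right so a boundary
sample belongs to the later phase (2000/600/2000 samples at 100 Hz).

The processing chain:

1. **Preprocessing.** Integer-stride down-sampling to 100 Hz followed by
   a 4th-order Butterworth low-pass at 20 Hz.  Filtering is zero-phase
   (forward–backward) by default so event-locked segment boundaries are
   not smeared by group delay; this doubles the effective attenuation
   (the 25 Hz gain of the digital design is ≈ 0.072).  A causal single
   pass is a flag.  Up-sampling is refused.
2. **Orientation.** A complementary filter: per-sample gyro strapdown
   integration corrected toward the accelerometer-implied gravity
   direction about a horizontal axis, so the correction fixes
   inclination only and heading evolves purely by gyro integration
   (no magnetometer; slow yaw drift is accepted over the ≤ 90 s task).
   The blending weight defaults to 0.02 per sample at 100 Hz (≈ 0.5 s
   time constant).  Samples with near-zero specific-force norm
   (< 0.05 g, free fall) skip the correction.  Initial tilt comes from
   the mean accelerometer vector over the first 0.5 s, with zero
   initial yaw.
3. **Channels.** Acceleration and angular velocity are resolved in a
   world frame with z up: `ah`/`omegah` are horizontal magnitudes,
   `av` is vertical acceleration minus 1 g (9.80665 m/s²), `omegav`
   the vertical rate component, `alpha` the tilt of the device axis,
   and `gamma` the unwrapped heading reported as unsigned deviation
   from the initial heading (0–180°+ scale).  Angles are in degrees,
   accelerations in m/s².
4. **Features.** 29 per channel × 6 channels = 174 per phase: nine
   amplitude statistics (mean, RMS, skew, kurtosis, range, max, min,
   SD, peak-to-RMS), seven band powers (0–0.5, 0.5–1.5, 1.5–5, 5–10,
   10–15, 15–20, > 20 Hz), the locations and heights of the first six
   periodogram peaks by ascending frequency, and the zero-lag
   autocovariance.
5. **Classification.** Leave-one-subject-out cross-validation.  Inside
   every fold: z-scoring (sample SD), univariate two-class
   Davies-Bouldin ranking of all features, the 10 best-separating
   features, and an unregularized maximum-likelihood logistic
   regression.  The held-out subject is scored with the training fold's
   parameters only.  Metrics at score threshold 0.5 (a more liberal
   screening point, 0.375, is an option); ROC by threshold sweep, AUC
   by trapezoid (equal to rank concordance with half credit for ties).
6. **Chance test.** The observed error count k of n is expanded into
   m = 100 draws from Beta(k+1, n−k+1); the null is m full-pipeline
   reruns under uniform label permutations; the two samples are
   compared two-sided with the Wilcoxon signed-rank on index pairs
   (unpaired Mann–Whitney U by option).
7. **Questionnaire comparator.** CBCL T-score cutoffs (clinical ≥ 70,
   screening ≥ 55, inclusive) against the diagnosis label, plus the
   threshold-free AUC of the continuous T score.  Missing scores are
   excluded listwise per scale and the analysed denominator is always
   reported, because cutoff metrics are not interpretable without it.

## Numerical and design choices

* **Feature composition.** The 9 + 7 + 12 + 1 block structure is the
  canonical reconstruction consistent with a 29-feature-per-channel
  budget that includes a 6th spectral peak and the zero-lag
  autocorrelation height.  Kurtosis is non-excess (Gaussian → 3) and
  skew/kurtosis of a zero-variance series map to 0; peak-to-RMS is 0
  when RMS is 0.  The spectrum is the one-sided periodogram of the
  mean-removed series with a rectangular window (0.05 Hz resolution for
  a 20 s phase), scaled so the bin powers sum exactly to the biased
  variance; the seven bands partition the bins (half-open intervals,
  Nyquist closed), so band powers always sum to total power.  Peaks
  are strict local maxima above a 1e-12 relative floor (guarding
  against numerically-zero bins); fewer than six peaks pad with (0, 0).
  The zero-lag autocorrelation uses the biased, mean-removed estimator
  — a normalized estimator would be identically 1 and carry no
  information.
* **Davies-Bouldin scatter.** q = 1 (mean absolute deviation), the
  classical formulation, with q = 2 as a config option; scoring is
  univariate per feature (no subset search), with stable tie-breaks on
  column order and +inf for zero centroid separation so constant
  features rank last.
* **Logistic solver.** IRLS, tolerance 1e-8, 100 iterations.  With
  ~60 subjects and 10 selected predictors, complete separation is
  common (virtually always under strong planted effects and often in
  permuted runs); it is detected by non-convergence or runaway
  coefficients and handled by a ridge refit (λ = 1e-4), keeping every
  fold finite and the permutation null well defined.
* **Beta shape.** Beta(k+1, n−k+1) (Bayes–Laplace), which is proper at
  k = 0; the raw Beta(k, n−k) shape is available but rejected at the
  degenerate boundaries.
* **"Paired" rank test.** A paired Mann–Whitney U test is a
  contradiction in terms; the default is the Wilcoxon signed-rank on
  index-paired samples (both sides are i.i.d., so the pairing is
  arbitrary), with the unpaired U test as the alternative.

## The synthetic cohort

Real recordings of children cannot be shared, so the generator
prescribes world-frame motion and synthesises device-frame signals
from it (inverse construction → exact ground truth).  Defaults are the
study conditions: 21 cases / 41 controls, 100 Hz, 55 s recordings with
the startle at 30 s.  Cases execute a smooth sigmoidal heading turn
beginning half-way through Potential Threat with final yaw
N(160°, 30°) clipped to [90°, 350°]; controls wander to N(30°, 20°)
clipped below 58°, mirroring the observed pattern (affected children
turn away from the ambiguous threat, γ ≅ 180°, while controls stay
below 60°).  Clip bounds are spec fields, so a zero-effect cohort is
obtained by setting case parameters equal to control parameters.  Both
groups share sinusoidal postural sway (3° at 0.25 Hz about a random
horizontal axis), sensor noise (0.02 g accelerometer, 1 °/s gyro), and
an identical-in-distribution startle jolt (0.5 g damped 8–15 Hz burst,
0.3 s) that deliberately carries no diagnostic information.  All
randomness flows from one master seed through per-subject substreams.

What the generator does **not** emulate: gait and whole-body
biomechanics, linear accelerations of locomotion, gyro bias drift,
sensor-mounting variability, or any realistic overlap structure
between groups beyond the yaw-effect distributions.  Passing tests on
synthetic cohorts therefore demonstrate that the pipeline recovers a
planted avoidance effect of the published magnitude and that every
stage is leakage-safe and reproducible — they do not re-establish the
clinical performance figures, which require the recorded cohort.

A second, purely statistical generator emits Gaussian feature tables
with optional planted mean gaps; it is used where signal synthesis
would only add runtime (selection and chance-test operating
characteristics).

## Simulation sizes used by the test suite

The end-to-end recovery checks run the full raw-signal pipeline on the
default 62-subject cohort for 20 seeds (effect present and absent).
The chance-test operating characteristics (type-I rate on null
cohorts; planted-signal error vs the permutation null's 5th
percentile) use 100 replicates of scaled-down cohorts — 7 cases / 13
controls, 50 features, m = 40 permutations — a size chosen to keep
100×(m+1) cross-validated pipelines tractable while leaving the
binomial acceptance bands meaningful.

## Known limitations

* **Null behavior of LOSO with fold-internal selection.**  On
  zero-effect cohorts the out-of-fold scores are anti-correlated with
  the labels (features selected for spurious training-set separation
  revert on the held-out subject), so the null AUC distribution is
  wide and biased below 0.5 — measured full-pipeline null AUCs range
  ≈ 0.16–0.60 across 20 seeds.  This pessimistic bias is a documented
  property of cross-validation with internal selection, not leakage.
* **Anti-conservative chance test.**  Expanding a single observed
  error count into m beta pseudo-samples and rank-testing them against
  m permutation error rates treats pseudo-replicates as independent
  evidence; whenever the one observed draw sits off the permutation
  median — which happens by chance alone — the test rejects.  Measured
  type-I rate on null cohorts is ≈ 0.7 at nominal α = .05.  The
  procedure is implemented as published; for a calibrated test, compare
  the single observed error to the permutation distribution directly
  (the planted-signal check in the test suite does exactly this via
  the null's 5th percentile).
* Heading is gyro-only; over minutes-long recordings yaw drift would
  bias γ.  Irregular sampling is handled only by nominal-rate
  decimation; recordings with heavy timestamp jitter should be
  resampled upstream.
* The logistic model is linear in the selected z-scored features; no
  calibration of the output scores is attempted.
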