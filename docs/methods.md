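# Methods

## The problem and the fusion model

EEG indexes a driver's mental workload (MWL) reliably — frontal midline
theta power increases and parietal alpha power decreases under cognitive
demand — but continuous in-vehicle EEG is impractical.  The methodology
implemented here uses EEG once, to *calibrate*, and vehicular telemetry
thereafter.  Two artifacts come out of calibration:

1. an **EEG workload index**: a stepwise linear discriminant over
   IAF-anchored spectral features, trained on epochs from the least and
   most demanding conditions (Easy = 0, Hard = 1), smoothed by an 8 s
   moving average into `MWL_SCORE`;
2. an **MI template**: the matrix I(E, V) of pairwise mutual information
   (bits) between each of the 4 vehicular features and each of the 45 EEG
   band features, summarized by the Euclidean norm of each row.  At
   deployment a new, min–max-scaled vehicular feature vector v′ is weighted
   elementwise, m′ = v′ ⊙ ‖I(E, V)‖, giving 4 "MI-based" features that
   require no EEG.

MI is used instead of correlation because the EEG–vehicular dependence is
weak and nonlinear; MI captures any statistical dependence, and the row
norm aggregates a vehicular signal's total shared information with the
whole EEG feature set.  Note the projection rescales features by positive
constants: scale-invariant learners (trees) see exactly the information in
v′, while scale-sensitive learners see an MI-informed weighting.

## EEG processing chain

Fixed parameters follow the recording standard the method assumes:
15 channels (Fpz, Fz, Pz, POz, Oz, AF3, AF4, F3, F4, P3, P4, P5, P6, O1,
O2) at 256 Hz.

* **Filtering** — fourth-order Butterworth band-pass 1–30 Hz, applied
  forward–backward (zero phase).  The chain is offline, so the doubled
  effective order and zero phase distortion are free improvements.
* **Blink correction** — blink intervals are detected on the 6 Hz
  low-passed Fpz reference by a 40 µV amplitude criterion (±0.1 s padding);
  within each interval every channel has its least-squares projection on
  the reference subtracted.  No samples are dropped.  This is a documented
  regression-based correction in the spirit of reference-channel blink
  removers; it assumes blinks are the dominant frontal transient and share
  a fixed topography.
* **Epoching** — 2 s windows advanced by 0.125 s (93.75 % overlap), 0-based
  half-open; the count for a T-second record is ⌊(T−2)/0.125⌋+1.
* **Artifact rejection** — an epoch is rejected if *any* channel (i) exceeds
  ±100 µV, (ii) has an ordinary-least-squares trend steeper than 10 µV/s
  (the standard reading of a "slope after interpolation" criterion), or
  (iii) contains a sample-to-sample step above 25 µV.  Criteria are applied
  after filtering and blink correction.  On simulator sessions at the
  default noise level the rejected fraction is ≈ 30 %: the synthetic 1/f
  background keeps substantial 1–2 Hz power, which the 10 µV/s trend
  criterion catches often.  The fraction is a property of the data, not of
  the mechanism; the criteria themselves are verified exactly on
  constructed epochs.
* **PSD** — per-epoch, per-channel Hann-windowed periodogram (512-point,
  0.5 Hz bins).  A Parseval identity against windowed time-domain power is
  part of the test suite.
* **IAF** — peak of the epoch- and channel-averaged resting ("closed
  eyes") PSD restricted to [8, 12] Hz, over the posterior channel set.
  Band edges then follow: theta [IAF−6, IAF−2], alpha [IAF−2, IAF+2], beta
  [IAF+2, IAF+18]; band-edge bins are inclusive, which yields 17 bins from
  IAF−6 to IAF+2 and 9 bins per sub-band.
* **Feature matrices** — `band45`: mean band power for 3 rhythms × 15
  channels, feature IDs channel-major (theta@Fpz = 1 … beta@O2 = 45);
  `roi187`: raw PSD bins for 5 frontal (Fz, AF3, AF4, F3, F4) + 6 parietal
  (Pz, POz, P3, P4, P5, P6) channels × 17 bins.  Fpz is excluded from the
  frontal ROI because it serves as the blink reference — the only
  assignment consistent with 45 frontal-theta + 54 parietal-alpha = 99
  selectable columns out of 11 × 17 = 187.

## Stepwise workload index

The discriminant is the classical regression formulation of stepwise LDA:
0/1 labels regressed on ROI columns.  Forward step: admit the eligible
candidate with the lowest residual sum of squares if its partial-F p-value
is ≤ `p_enter` (0.05) *and* the BIC improves; backward step: drop any
included feature whose removal p-value reaches `p_remove` (0.10); stop when
no candidate qualifies.  The automatic stop (partial-F + BIC guard) is this
package's documented stopping rule; all three constants are exposed.  If
the procedure admits nothing (pure-noise input) the single best candidate
is kept so the model remains scorable, and the fallback is recorded in the
training trace.  Final weights and bias are the least-squares fit on the
selected columns, so class centroids score ≈ 0 and ≈ 1; scores are not
clipped.  `MWL_SCORE` is a trailing (causal) moving average over
round(8 / 0.125) = 64 epochs with an expanding-window warm-up — trailing
because the index is meant to be computable online.

## MI estimation

* **Histogram (default)** — plug-in Shannon entropy on an equal-width grid,
  16 bins per axis over [0, 1] (inputs are min–max scaled), log base 2.
  H(Y|X) and I(X;Y) are computed from a single joint table, which makes
  H(Y|X) ≤ H(Y) an identity and I ≥ 0 and symmetry exact.  On genuinely
  discrete data with one value per bin the estimator coincides with the
  discrete definition to machine precision.
* **k-NN** — Kozachenko–Leonenko differential entropy and the Kraskov
  (algorithm 1) MI estimator, k = 3, Chebyshev balls; negative MI estimates
  are clamped to zero.  Used where differential quantities are needed
  (Gaussian closed-form checks: H = ½log₂2πe ≈ 2.047 bits,
  I(ρ=0.9) = −½log₂(1−ρ²) ≈ 1.198 bits).

Both estimators are positively biased at independence; the empirical 95th
percentile of MI between independent uniforms at the working sample size
(`independence_bias_floor`) is the yardstick for "≈ 0" statements.  When
epochs overlap by 93.75 % the effective sample size is ~16× smaller than
the row count, inflating that floor accordingly.  Row norms are Euclidean
by default (L1 available).  The template is always fitted on training rows
only and stores its scaling ranges, since it is the deployable artifact.

Projection form: the template weighting is elementwise (m′ = v′ ⊙
row-norms), keeping 4 MI-based features — the only reading consistent with
a fixed 4-feature MI-based set; a scalar dot-product variant is available
behind `mode="dot"` for comparison.

## Evaluation harness

Model hyperparameters are fixed: LnR (OLS), LgR (balanced class weights,
L2), MLP (hidden layers 32/16/4, ReLU, Adam, batch 128, 500 epochs, tol
1e-4), RF (100 trees, depth 5, bootstrap), SVM (RBF, degree 3, C = 1.0,
ε = 0.2 for regression).  Schemes: shuffled 10-fold CV,
leave-one-subject-out, stratified 10 % holdout.  Metrics report undefined
ratios as `None`, never 0.  AUC is the Mann–Whitney statistic with ties
counted half; the Wilcoxon signed-rank test enumerates all 2ⁿ sign
patterns for n ≤ 12 (exact even under tied ranks) and otherwise uses the
normal approximation with tie and continuity corrections; DeLong's test
uses placement-value (structural-component) variances, one-sided by
default.  For n = 9 uniformly positive differences the exact two-sided p
is 2/512 ≈ 0.0039.

## The synthetic-data generator

No driving dataset accompanies the methodology, so the generator *defines*
the study conditions and supplies ground truth.

* **Latent trace** — piecewise baseline from the schedule: Easy 0.42,
  Hard 0.51 (the reported group means), +0.05 during Rush hour, +0.06
  (Car) / +0.14 (Pedestrian) during events — a mean event increment of
  +0.10 with a type contrast chosen because event types differ far more in
  vehicle response than in mean workload; plus AR(1) noise with stationary
  sd 0.10 and coefficient 0.9998 at 256 Hz (≈ 20 s autocorrelation time).
  The 20 s scale matters: an index with 8 s resolution computed from 93.75 %
  overlapping epochs averages only ~4 independent periodograms, so workload
  fluctuations much faster than ~10 s are untrackable by construction and a
  faster trace would cap the achievable index–trace correlation near 0.5
  regardless of spectral SNR.
* **EEG** — per channel: 1/f background (12 µV RMS), a theta oscillation at
  IAF−4 Hz on frontal channels with amplitude 2 + 10·w(t) µV, an alpha
  oscillation at IAF on parietal/occipital channels with amplitude
  2 + 10·(1−w(t)) µV (tripled in the closed-eyes resting mode), blink
  transients (400 ms raised cosine, 80 µV at Fpz, fixed topography) at a
  Poisson rate, and sparse 0.5 s high-amplitude bursts.  Amplitudes are
  within physiological ranges and give per-epoch band-power SNR at which
  the calibrated index tracks its own ground truth.
* **Vehicular** — velocity = segment baseline (Easy 44.69, Hard
  37.81 km/h, the reported group means) − c · 40 km/h · (w(t) − segment
  mean) + smoothed noise (sd 2 km/h); acceleration is the first difference
  of velocity; lateral/longitudinal accelerations are c-weighted
  band-passed (0.05–1 Hz) functions of the trace (gains 8 and 5) plus
  noise (sd 0.2).  c = 0 detaches every channel from the trace exactly.
  The 40 km/h gain makes the workload-mediated velocity response of the
  order of the few-km/h contrasts a real study reports.

What the generator does **not** emulate: volume conduction and channel
covariance, non-stationary alpha reactivity, realistic road geometry,
driver-specific control styles, measurement dropouts.  Passing
recovery tests therefore shows the *pipeline* is correct and the method's
information flow behaves as designed — not that the method would reach any
particular accuracy on real drives.

### Known structural property of the coupling sweep

In the vehicular-only event-classification check (Car vs Pedestrian from
MI-projected features), both the discriminative signal (the event-type
contrast in the trace) and the dominant nuisance (trace wander) reach the
vehicular channels through the same coupling factor c, so their ratio is
c-invariant and only the fixed sensor-noise term makes AUC grow with c.
The AUC therefore rises sharply from chance at c = 0 and then saturates
between c = 0.5 and c = 1 (typical 3-seed means ≈ 0.46 / 0.64 / 0.66).
Monotonicity is asserted over a seed family with a 0.02 tolerance.
Because overlapping epochs within one 20 s event are near-duplicates,
folds split by event (never by epoch), with both classes present in every
fold; event types are balanced within each segment type so the segment
velocity baseline cannot leak the label.

## Problem sizes and numerical choices

* Test-suite sessions: 60–150 s per segment; the acceptance script uses
  three 150 s-segment laps (≈ 900 s, ~7000 epochs) for index recovery and
  a 2400 s vehicular-only session (60 events) per coupling level, averaged
  over 3 seeds.  The full suite runs in ~1.5 min, the acceptance script in
  ~2 min on one CPU.
* Index–trace correlations are computed at the index's own resolution
  (both series passed through the same 8 s trailing average); the raw
  per-epoch correlation is also ≥ 0.7 at the defaults.
* Stepwise selection recomputes OLS per candidate (99 candidates,
  a few thousand rows); no incremental QR is needed at this scale.
* The resampler centers signals before the polyphase filter so constant
  (DC) inputs are reproduced exactly.
* Min–max scaling learns ranges on training rows and clips test rows to
  [0, 1]; global scaling (which leaks across splits) is available but not
  default.
* Degenerate inputs raise: constant columns without supplied ranges, tied
  IAF peaks, single-class training labels, all-zero Wilcoxon differences.

## Limitations

* The stepwise stopping rule is this package's own (partial-F + BIC); the
  historical automatic-stop variant it stands in for is proprietary and may
  select differently.
* Histogram MI in bits depends on the bin count; reported template values
  are comparable only within one estimator configuration (recorded in
  `estimator_meta`).  Reported MI is always in bits and non-negative.
* Three published holdout-table cells disagree with their own confusion
  matrices by one unit in the second decimal; the recomputed values are
  taken as authoritative (see `miwl.study_data.PRINTED_ROUNDING_SLIPS`).
* Subject-level heterogeneity is limited to per-subject IAF and gain
  parameters; leave-one-subject-out validation on simulated "subjects" is
  supported but exercises less variability than real cohorts.
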