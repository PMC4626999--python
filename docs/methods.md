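# Methods

This note records the models, defaults and numerical choices behind
`ppgstress`, and what the synthetic experiments do and do not establish.

## Synthetic cohort model

Each subject contributes one rest recording (`BE`) and one recording per
post-exercise heat-stress stage (`E1`–`E3`), 20 s at 367 Hz.

**Beat timing.** Inter-beat intervals are i.i.d. Gaussian around the base
interval 60/HR with σ = RMSSD/√2 — the simplest process with a
closed-form RMSSD (for independent jitter, E[RMSSD] = √2·σ). Intervals
are floored at 0.3 × the base interval; a physiologically negligible
truncation at the default parameters.

**Subject parameters.** Per-subject heart rates are drawn truncated-normal
in (45, 200) bpm around the stage medians 76.0 (rest) and 132.0 / 145.5 /
143.0 bpm (stages 1–3), with normal-equivalent dispersions IQR/1.349
using the cohort IQRs 17.5 / 44.3 / 40.3 / 40.2 bpm. RMSSD targets are
40 ms at rest and 15 ms under stress — no published values exist for this
contrast, so these are configuration knobs chosen to give clear but
overlapping class separation — scaled by a shared subject-level lognormal
trait (σ_log = 0.3) so a subject's rest and stress recordings are
correlated.

**Waveform.** Each beat is a systolic Gaussian (σ = 50 ms at rest,
42 ms under stress) plus a dicrotic Gaussian 1.6× wider, delayed by 35 %
of the local beat interval, with relative amplitude 0.35 (rest) / 0.15
(stress). The heat-stress morphology shift (weaker dicrotic wave,
narrower systolic peak) is asserted only qualitatively by the physiology
literature, so its magnitude is a knob, not a claim. A per-recording
lognormal amplitude factor (σ_log = 0.1) emulates sensor-coupling
variation. Ground-truth systolic peak times are recorded as the realized
local maxima of the clean waveform; beats truncated by the window edge
are not annotated.

**Noise.** Three additive sources: a baseline-wander sinusoid with
frequency drawn in 0.2–0.4 Hz (amplitude 0.20 of the unit pulse), a
50 Hz powerline sinusoid (0.02) and white Gaussian noise (σ = 0.02).
With all amplitudes zero the generator output is exactly the clean
waveform.

**What the generator does not emulate:** motion artifacts, waveform
non-stationarity within a recording, respiratory sinus arrhythmia
(jitter is white, not oscillatory), device transfer functions, and any
true physiological coupling between heart rate, HRV and pulse contour.
Passing end-to-end tests therefore demonstrates that the pipeline
recovers the statistical structure it assumes — not that the specific
derivative orders found optimal here would be optimal on real
recordings.

## Preprocessing

The "filtered" branch band-passes with a Butterworth filter designed as
`butter(2, [0.5, 7] Hz)` — four poles overall, which is what the
biosignal literature and MATLAB both call a *second-order* band-pass.
The default pass is causal with the filter state initialized to the step
steady state (`sosfilt_zi · x[0]`), which suppresses the multi-second
startup ring the 0.5 Hz corner would otherwise produce; a zero-phase
forward–backward mode is available and is the default for peak
detection, where group delay would bias peak times. The filter is
realized in cascaded second-order sections: at fs = 367 Hz a direct
transfer-function form of the 0.5 Hz corner is ill-conditioned. No
samples are trimmed after filtering.

## Derivatives and double precision

The cascade applies the scaled backward difference
(S[n] − S[n−1])/T recursively; each order shortens the signal by one
sample (padding would inject discontinuities that explode after 20
differentiations). The 1/T = 367 scaling is applied at every step as the
defining formula states; it is uniform across recordings and therefore
irrelevant to the rank-based statistics, but it sets the absolute scale
of the features (order-20 magnitudes reach ~1e50 for in-band content;
their squares stay below the ~1.8e308 double-precision ceiling).

One genuine double-precision limit is worth recording: the per-step
amplitude gain is 2·fs·sin(πf/fs), which is 2·fs at Nyquist but only
~44 at 7 Hz. Quantization noise of the *input* (relative ~1e-16, spectrally
flat) is therefore amplified relative to a 7 Hz component by ~16.7× per
order, overtaking it after ~12 orders no matter how the cascade is
implemented. The closed-form gain oracle in the tests is consequently
checked at 7 Hz up to order ~10 and at 50 Hz (ratio 2.4×/order) up to
order 20, using least-squares sinusoid projection to measure the
component amplitude. For real, noise-bearing recordings this is
immaterial — measurement noise sits far above the quantization floor —
but it means very-high-order features of *clean narrowband* signals are
numerically noise-dominated.

## Features

"Normalized" energy and entropy refer to the 1/N factor; N is the length
of the order-j signal (which shrinks with j), since the defining sums
run over the signal being summed. The entropy uses the 0·ln 0 := 0
convention and may be negative (it is a signal-randomness functional on
squared amplitudes, not a probability entropy). No amplitude
pre-normalization is applied by default; a per-recording unit-variance
flag exists for cross-device scenarios and is off by default because the
defining formulas contain none.

## HRV

Peak detection squares the (zero-phase-filtered, negative-clipped)
signal and compares a 111 ms moving average against a 667 ms moving
average plus 0.02 × the mean squared signal; suprathreshold blocks at
least one peak-window wide contribute their waveform argmax, with a
250 ms refractory rule keeping the larger of two close candidates.
RMSSD is the standard root mean square of successive inter-beat-interval
differences, in ms; intervals outside (0.25, 2.0) s are discarded first
because a single missed beat in a 20-s window would otherwise dominate,
and differences are taken only between intervals adjacent in the
original beat sequence. A literal "RMS of the intervals" variant exists
as a debug option only.

## Screening

The Mann–Whitney p-value is exact (full enumeration) when the combined
sample size is ≤ 12 without ties and otherwise uses the tie-corrected
normal approximation with continuity correction; the cutover is a cost
choice, pinned by enumeration oracles below it. The default Holm family
is every test computed in a run — 2 features × 2 statuses × 21 orders ×
3 comparisons = 252 for a full scan; a 240-test family (excluding order
0) is available as a config option since the order range and the stated
test count cannot both hold. The unpaired two-sided test is the default;
a paired Wilcoxon signed-rank option exists for subject-matched
contrasts.

## Classification

LDA, QDA and the Mahalanobis-distance rule are closed-form Gaussian
discriminants with equal priors (the design is balanced): per-class
means and unbiased covariances, pooled for LDA, with the QDA score
adding the log-determinant term. Implementation notes that matter:

* features are standardized per column inside the rule (the Gaussian
  rules are affine-equivariant, so this changes nothing in exact
  arithmetic but keeps the astronomically scaled high-order features
  well-conditioned next to RMSSD);
* columns constant across the training set are dropped (they carry no
  class information, and regularizing them would distort the QDA
  log-determinant);
* a trace-scaled ridge (1e-6, escalated tenfold on failure) is added
  only when the covariance is not positive definite;
* ties predict the rest class, deterministically.

The test suite pins LDA/QDA to scikit-learn's implementations by exact
prediction agreement. The linear SVM (C = 1) is scikit-learn's, with
per-fold standardization computed from training-fold statistics only.
Cross-validation is leave-one-recording-out, matching a design in which
each recording is a unit; a subject's rest and stress recordings are not
independent, which is a known limitation of that scheme, and
leave-one-subject-out is left to the caller by filtering the dataset.

F1 is reported as 0 (flagged) when SE + PP = 0.

## Scan and combined detector

The scan evaluates every cell per comparison (rest vs each stage) and
summarizes a cell by its mean OA across comparisons; the per-block and
global optima are argmaxes of that mean. The combined detector is fixed
to (entropy, filtered, order 7) + RMSSD under QDA; because on synthetic
data the data-selected optimum usually differs, the results object
reports both the fixed cell and the scan's own optimum. Recordings
without a valid RMSSD are excluded with a count; more than 20 % excluded
is a hard error. If the requested combined-cell order exceeds the
scanned range it is clamped to the highest scanned order.

## Problem sizes

Default study conditions are 40 subjects × 4 conditions × 20 s. The
test suite exercises the full-size end-to-end recovery over 5 seeds,
and scales supporting Monte-Carlo checks to what they need: null-cohort
type-I calibration uses 200 cohorts of 10 subjects with derivative
orders 0–6, pipeline smoke tests use 6–8 subjects with reduced order
ranges. These sizes are stated here as the package's own test design.

## Known limitations

* Synthetic-only validation; no real-device ingestion.
* The white-jitter IBI model understates the spectral structure of real
  HRV, so RMSSD here is cleaner than in field recordings.
* High-order (≳12) features of the filtered branch are dominated by
  amplified broadband noise (physical or numerical), which is faithful
  to the recursive-difference definition but means those cells rarely
  win on synthetic data.
* The paired structure of the cohort is ignored by the default unpaired
  screening test, mirroring the analysis design the pipeline reproduces.
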