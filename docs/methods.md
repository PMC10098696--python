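# Methods

## Signal model and preprocessing

**Segmentation.** Both channels are cut into 60-s windows tiled inside each
protocol interval. One minute is long enough for short-term
pulse-rate-variability (PRV) statistics and matches the shortest protocol
task. Windows that would straddle a rest/task boundary are dropped rather
than assigned a mixed label, and interval tails shorter than a window are
discarded; this keeps every window's label well defined at the cost of a few
segments per session.

**PPG filtering.** Segments are band-passed with a Chebyshev type-II filter,
order 4 overall (second-order per band edge), 20 dB stopband attenuation,
passband 0.5–5 Hz. A named filter family with these constraints still leaves
the transition widths open; we anchor the *passband*: the stopband edges
(0.23171 and 10.0964 Hz, solved at 64 Hz) are chosen so the single-pass
−3 dB points land exactly on 0.5 and 5 Hz. Anchoring the stopband closer to
the passband instead (e.g. edges at 0.4/6 Hz) would attenuate 4 Hz content —
well inside the nominal passband — by ≈ 7 dB, which contradicts the stated
passband. The filter is applied forward–backward (zero phase), so peak
*times* are unbiased while effective attenuation doubles.

**Peak detection and interval validation.** Pulse peaks are strict local
maxima above 0 with a 0.4-s minimum separation; among conflicting candidates
the higher survives (highest-first pruning, the behavior of MATLAB
`findpeaks` and `scipy.signal.find_peaks`). Successive peak differences in
ms form the PP series; intervals outside the closed range [500, 1200] ms
(instantaneous rates above 120 or below 50 bpm) are excluded as abnormal. A
segment is accepted iff abnormal intervals are strictly fewer than 15% of
all intervals. The 15% rule is by *count*; because a handful of very long
abnormal intervals can carry much more than 15% of the time while staying
under 15% by count, the count rule alone does not guarantee the usual
">50 s retained" justification. We therefore also expose a
duration-weighted variant (`fraction_mode="duration"`), under which a 60-s
segment at the worst accepted fraction retains 60 × 0.85 = 51 s > 50 s
exactly. Segments with fewer than two detected peaks have no PP series and
are rejected outright.

**EDA chain.** The 4-Hz channel is linearly upsampled to 64 Hz (integer
multiple enforced by default; duration preserved; the last sample is held,
never extrapolated) and smoothed with a 40-point Gaussian kernel of
σ = 400 ms. At 64 Hz, σ is 25.6 samples — wider than the 40-point window —
so the kernel is aggressively truncated; it is renormalized to unit sum so
the tonic level is preserved. SCR events are detected on the driver trace:
the first difference convolved with a 20-point Bartlett window.
Differentiation and convolution commute as linear operators, so the order
only affects edge samples; we difference first. An event opens at an upward
zero-crossing of the driver and closes at its next non-positive sample,
which inherently merges compound SCRs (a re-rise before recovery extends the
open event). Onset = opening sample, peak = signal maximum inside the event,
amplitude = signal(peak) − signal(onset), rise time = peak − onset, duration
= onset to driver recovery. Events below 0.01 µS — the conventional SCR
minimum; no floor is inherent to the operator — are discarded.

## Features

27 per accepted segment, in fixed order: 16 PPG-derived (Mean_PP, std_PP,
M_HR, std_HR; HF; SD2; mean/median/mode/min/max/SD of the filtered BVP and
mean/SD of its first and second differences), 6 EDA statistics, 5 SCR
summaries (mean duration/amplitude/rise time, count, mean of the driver
trace). Numerical choices:

- Standard deviations use the sample (n−1) denominator throughout.
- The HR series is 60000/PP per beat, so M_HR is the mean of instantaneous
  rates (not 60000/Mean_PP).
- **HF power**: the PP tachogram is cubic-spline interpolated onto a uniform
  4-Hz grid against cumulative beat time, mean-removed, PSD estimated by
  Welch (32-s segments, 50% overlap), and integrated over 0.15–0.40 Hz
  (ms²). The band integral is the defined quantity; the estimator is the
  conventional HRV pipeline and is configurable. At least 8 retained
  intervals are required, else the segment is dropped from the table.
- **SD2** = (1/√2)·std(PPᵢ + PPᵢ₊₁); the coefficient is exposed as a
  parameter. Pure alternation cancels in the sums, so SD2 isolates
  long-term variability.
- **Mode** of a continuous signal is ill-defined; we round to 3 decimals
  and break ties toward the smallest value.
- **Difference features** are raw per-sample first/second differences of the
  filtered waveform (the `diff` convention): a ramp of slope s at rate r has
  M_d1 = s/r. An alternative — dividing by the sampling interval to get a
  derivative in units/s — only rescales the feature and is irrelevant after
  z-scoring.
- **SCR means** are zero-filled when a segment has no events (rest segments
  legitimately may have none); N_PEAKS is the count; M_SCR is the mean of
  the phasic driver trace over the whole segment (not of event peaks).

**Standardization.** Z-score per column. The scope is a parameter: fitted
inside each training fold (`per_fold`, leakage-safe default), fitted once on
the whole table before cross-validation (`pooled`, reproducing the
standardize-then-validate order some toolboxes use, which leaks mildly), or
off. Zero-variance columns are flagged and passed through unscaled.

## Feature ranking

**Chi-square.** Each feature is discretized into 10 equal-width bins over
its observed range (quantile binning available; it makes the score invariant
under monotone rescaling), crossed with the label, empty bins pooled out and
degrees of freedom reduced to (bins_used − 1). The score is −log p computed
via the log survival function, so perfect dependence yields a large finite
score rather than −log 0. The threshold is the mean score over the 27
features; selection is strict (> mean). The log base (default e) is
configurable because the mean-threshold rule — unlike pure ranking — is
base-sensitive. Under the null the score behaves approximately like an
Exp(1) draw, so the mean-threshold rule selects ≈ 1/e of null features; the
test suite checks this against a Monte-Carlo of the same rule.

**Pearson.** Score = |r| between feature and the numeric 0/1 label; features
with |r| ≥ 0.10 survive, ordered descending. The absolute value makes the
ranking sign-blind, as a correlation-based attribute evaluator is.

## Classification

Stratified k-fold (default 10) with a stored seed. Out-of-fold predictions
are pooled into a 2×2 confusion matrix; per-fold accuracies are kept
alongside and `summary()` quotes their mean (the two differ only by fold-size
weighting). Metrics are computed per label by swapping the positive class;
empty-denominator precision/recall is reported as 0 with an explicit flag.

Hyperparameter mapping: "number of splits" bounds the per-tree decision
splits (realized as `max_leaf_nodes = splits + 1`), "learners" is the
ensemble size; the cubic SVM uses kernel (x·y/s² + 1)³ with box constraint C
and kernel scale s; logistic regression is deliberately untuned. With range
enforcement on, learners must lie in [30, 100], splits in [500, 1000] and
kernel scale in [1, 10]. Per-feature-set defaults: all features — RF 50
learners/1000 splits, SVM scale 7; chi-square set — RF 100/500, SVM scale 3;
Pearson set — RF 50/1000, SVM scale 3.

`StressExperiment.fit()` evaluates every (feature set × family) cell and
returns a results object carrying the reports, the selection results and a
long-form `summary()` grid; confusion-matrix heatmaps hang off the results
object.

## Synthetic data

The generator emulates the physiological contrast a rest/task stress
protocol elicits, not cardiovascular or sudomotor biophysics:

- **PPG**: beats placed sequentially with PP = 60000/HR(label) plus Gaussian
  jitter truncated to > 300 ms; each beat is a fixed two-Gaussian template
  (systolic peak + dicrotic bump ≤ 0.4 of the main peak, so the 0.4-s
  distance rule suppresses the bump); baseline wander below 0.5 Hz plus
  white noise; motion artifacts as high-amplitude 3–5 Hz oscillatory bursts
  — deliberately inside the passband so they both spawn spurious peaks and
  mask true beats, exercising both abnormal-interval branches.
- **EDA**: tonic level with slow drift; SCRs as bi-exponential transients
  (rise 1–3 s, decay 4–10 s, amplitude uniform in 0.1–0.8 µS) placed by a
  label-dependent process with shifted-exponential gaps — mean gap exactly
  1/rate but never below 6 s, so nominal rates are honored while every
  injected event remains individually identifiable ground truth; plus
  measurement noise. Inter-event gaps are drawn at the rate in force at the
  previous event, so a few task-rate events spill into the first seconds of
  each rest block — mirroring the carry-over real protocols show.
- Defaults are the study conditions: rest HR 65 bpm, +15 bpm under stress,
  PP jitter 40/25 ms (rest/stress), SCR rates 2 vs 6 per minute, tonic
  2 µS, 1 motion artifact per minute, and a 320:523 rest:stress row
  imbalance in the direct feature-table sampler.

What passing tests on this generator show: the measurement chain recovers
what was injected (peaks, intervals, SCR events, group contrasts) and the
decision rules behave as specified. What they do not show: performance on
real wearable data — real PPG morphology, correlated motion artifacts across
channels, non-stationary tonic EDA and individual differences are all absent,
and the near-perfect synthetic classification accuracies carry no information
about accuracy on real recordings.

**Recovery checks** are run on artifact-free subjects: they measure chain
fidelity, while artifact handling is tested separately (heavy-artifact
sessions must lose segments to the 15% rule; at the default 1/min an
occasional accepted segment's M_HR deviates from truth because retained
intervals can still straddle an artifact — a real property of the count
rule, visible in the test suite's tolerances).

## Problem sizes

Tests and the acceptance script use one or two ~34-minute synthetic sessions
(34 one-minute segments each), feature tables of 400–843 rows, and 10-fold
cross-validation of the three families — sizes chosen to estimate every
reported quantity stably while keeping the whole suite under a minute of
compute.

## Known limitations

- The chi-square score's equal-width binning is sensitive to outliers;
  quantile binning is provided but not the default (the default mirrors
  common univariate-ranking toolbox behavior).
- SCR "duration" is onset → driver recovery; other conventions (onset → 50%
  recovery) yield systematically shorter durations.
- The E4 reader handles BVP/EDA single-column exports only (no TEMP/ACC/IBI,
  tags, or streaming).
- Filter stopband edges are solved for 64 Hz; at other rates the −3 dB
  points shift slightly with bilinear prewarping.
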