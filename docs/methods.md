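# Methods

This note documents the models, estimators and numerical choices behind
`ssvep_tcsc`, and what the synthetic cohort does and does not establish
about real recordings.

## Stimuli and the reference sensitivity curve

Stimuli are square-wave luminance flicker at frequency `F` (Hz) and
Michelson modulation depth `MD = (Lmax − Lmin)/(Lmax + Lmin)` around an
average luminance `AvgLL` (default 1000 lx):

    waveform(t) = AvgLL · (1 + sgn(sin(2π F t)) · MD)

The sign at exact zero crossings is taken as +1 (half-open duty
convention); this touches at most two samples per cycle and keeps the duty
cycle at 1/2 up to one sample per half period.  Four experiment designs
sample (F, MD) cells: two express MD as multiples (0.4–12.8×) of the
visibility threshold of a reference temporal contrast sensitivity curve
(TCSC), one uses an absolute MD ladder (0.002–0.026).  Condition counts
are 25, 25, 30 and 30; default cohort sizes 10, 12, 24 and 16 subjects
(62 in total); every condition repeats 10 times.

The reference TCSC is the cubic/linear rational polynomial

    TCSC(f) = scale · (p1 f³ + p2 f² + p3 f + p4) / (f + q1)

with the psychophysical coefficient set (p1 = −0.0008, p2 = −0.409,
p3 = 40.68, p4 = 121.50, q1 = 10.75) on the domain [1, 60] Hz.  Direct
evaluation of these coefficients peaks near 18 Hz at a value of ≈ 24.9,
an order of magnitude below the peak sensitivity of 309 the curve is
known to reach, so the default curve keeps the printed shape and sets
`scale` so the peak equals 309; the electrophysiological set (0.014,
−1.69, 71.75, 155.90, 22.65) is anchored to its peak of 258 the same way.
Only the *shape* (and hence the peak location and threshold ratios across
frequency) is meaningful below that anchoring choice.  Queries outside
the domain raise rather than extrapolate.  User-supplied curves load from
CSV (tabulated, interpolated linearly in log–log coordinates) or JSON
(rational coefficients).

## Flicker visibility measure (FVM)

A square wave's Fourier components relative to DC are `C_m = (4/π)·MD/m`
for odd `m`.  The FVM is the Minkowski summation

    FVM = ( Σ_m (C_m / T_m)^p )^(1/p),   p = 2 (configurable),

with `T_m` the visibility threshold at the component frequency; FVM < 1
means invisible, 1 just visible, > 1 visible.  Components above the
curve's domain (harmonics above 60 Hz) contribute nothing — sensitivity
is vanishing there and no reference values exist; components below the
domain raise.  `T_m` carries the semantics of the supplied curve
(sine-wave thresholds for the default rational curve).

## Synthetic EEG cohort

The generator produces, per trial, a 3-s baseline and a 3-s stimulation
epoch with known ground truth:

- **Background**: random-phase noise with amplitude spectrum ∝ 1/f^α
  (α ≈ 1, subject-jittered) plus a Gaussian alpha bump (peak ~N(10, 1) Hz,
  1.5 Hz width), scaled to 10 µV RMS.
- **Response**: sinusoids at harmonics h·F < 128 Hz with total amplitude
  `A = gain · max(0, log10(MD/θ_eeg(F)) + c0)` — linear in log contrast
  above an onset slightly below the subject's electrophysiological
  threshold θ_eeg.  The amplitude is distributed over harmonics with
  weights ∝ 1/(1+|h−h*|)²; the dominant harmonic h* is the fundamental at
  F ≥ 20 Hz and the even harmonic nearest 40 Hz below that (ties to the
  smaller harmonic), reproducing the empirical pattern that low-frequency
  flicker responds strongest at gamma-band even harmonics.
- **Reports**: yes/no answers from a probit observer,
  `p = γ + (1−γ−λ)·Φ((MD−θ_psy)/(0.15·θ_psy))`, with guess and lapse
  rates γ = λ = 0.02.
- **Thresholds**: θ_psy is the reference threshold with ~15% log-normal
  subject jitter; θ_eeg = κ(F)·θ_psy with κ interpolating from 1.2 below
  45 Hz through 1.0 at 50 Hz to 0.8 at 60 Hz, so the electrophysiological
  curve sits below the psychophysical one at low frequencies and crosses
  it near 50 Hz.

Two constants deserve justification.  The onset offset `c0 = 0.05` places
the zero-amplitude point at `10^−0.05 ≈ 0.89·θ_eeg`: the z-score detector
(below) crosses chance level where the response amplitude vanishes, so
the offset is what ties the generative threshold to the estimator's 50%
point; a large offset would displace the two by construction.  The gain
default (6 µV per log10-contrast unit, ~20% subject jitter) puts the
response at threshold on the order of the background's per-bin amplitude
in a 1-s window at gamma frequencies — the near-threshold regime the
detection statistics are designed for.  Larger gains make detection
saturate within the sampled grid (separated psychometric fits), smaller
ones leave it indistinguishable from chance.

Seed hierarchy: master seed → experiment → subject → trial; every trial
records its own seed and is regenerable in isolation.  Generation modes:
`epochs` synthesises directly at 256 Hz (default for simulation studies);
`continuous` synthesises an uninterrupted 2048 Hz recording with event
markers so the full conditioning chain is exercised.

What the generator does **not** emulate: eye blinks and muscle artifacts
(the ICA stage is therefore a hook, not an implementation), volume
conduction and realistic channel covariance (the optional multi-channel
mode adds spatially scaled copies only), non-stationarity, adaptation, and
response saturation at high MD.  Passing recovery tests therefore show
that the estimator chain is consistent under its own assumptions, not
that those assumptions hold for any particular recording.

## Preprocessing

Notch (second-order IIR, Q = 30, 50 Hz) → polyphase resampling to 256 Hz
→ high-pass FIR (Hamming window, 1–2 Hz transition band, 845 taps), all
applied forward–backward for zero phase.  Common average referencing is
the identity (with a warning) on single-channel data.  Epochs are the
half-open windows [onset−3 s, onset) and [onset, onset+3 s); truncated
trials are dropped and logged.  Artifact rejection is a single pass per
condition: trials whose stimulation-epoch broadband variance at the
analysis channel exceeds the condition mean + 2 SD are removed (the epoch
kind and channel are configurable; with i.i.d. Gaussian epochs the
expected rejection rate is the ~2–5% upper tail).

## Detection statistics

Each 3-s epoch at 256 Hz is analysed in three non-overlapping 1-s
rectangular FFT windows (1 Hz bins, 1–128 Hz, no detrending); the per-bin
value is log10 of the mean amplitude over the three windows.  Per
condition:

- Cohen's d per bin between stimulation and baseline epochs, with the
  classical pooled SD; zero-SD bins get d = 0 with a warning.
- The best harmonic is argmax of d over h·F bins (h ≤ 10, h·F < 128 Hz),
  computed from FVM-visible conditions only (ties → smaller h).  When no
  condition at a frequency is FVM-visible, the largest-MD condition is
  used and logged.
- Per-epoch z-scores at the best bin against the baseline mean and SD;
  a trial counts as detected iff z > 0 (strict).  Under the null this
  fires at chance; the empirical rate is ~0.52 rather than exactly 0.5
  because log-amplitude means are mildly skewed.

Per-frequency quality control: each subject's global argmax bin of d over
[3, 127] Hz should land on an expected harmonic bin; a frequency is
excluded when the aligned fraction falls below 0.25 **or** the mean
best-harmonic d falls below 0.05 (both thresholds configurable — the
exclusion this mirrors was judgment-based).  Harmonic bins are exact
integer-Hz bins; all stimulation frequencies are integers.

## Psychometric thresholds

Detection probabilities per MD (subjective reports or z-score detections,
rejected trials excluded from the denominators) are fitted with a
binomial GLM, probit link, linear predictor in raw MD (log-MD optional).
The threshold is −β0/β1 (p = 0.5); fits are invalidated by non-positive
slope, non-positive threshold, residual deviance ≥ 1 (read literally as
total deviance, not per df), or separation/non-convergence.  The deviance
gate is strict: a well-specified binomial fit with k residual df has
expected deviance ≈ k, so with 5–6 MD levels roughly half to two-thirds
of honest fits are rejected; the gate effectively keeps the steep, clean
curves.  No lapse/guess parameters are fitted, so the observer's small
lapse rate acts as a realistic misspecification.

The z > 0 rule has a structural false-alarm floor of 0.5, which a plain
probit cannot represent; electrophysiological fits therefore only pass
the gates where the response onset sits near the bottom of the sampled MD
grid, and the threshold-relative designs (0.6–1.4× threshold) are the
appropriate recovery benchmark.  On the coarse absolute-MD ladder the 50%
crossing snaps to the lowest grid point — a property of grid placement,
not of the estimator.  At default settings, recovery on a 12-subject
relative-grid cohort gives a median relative threshold error of ~3%
(subjective) and ~20% (electrophysiological, negatively biased by the
floor).

## Curve fitting and comparison

Valid per-subject sensitivities (1/threshold) are pooled per frequency
with a single-pass 2-SD outlier exclusion (≥ 3 records required, sample
SD).  The rational polynomial is fitted to the pooled means by
Levenberg–Marquardt; initialisation solves the linearised system
`S·(f+q1) = p1 f³ + … + p4` by OLS over candidate q1 ∈ {1, 5, 10, 20, 40}
and starts from the best.  The fit is on linear sensitivities (Eq. form
is stated for the curve directly); R² is reported both against mean
sensitivities and against mean thresholds, since either reading is
defensible.  The coefficient vector of a rational fit is not unique —
tests assert curve equality, not coefficient equality.

Observation-level prediction bounds use the delta method,
`ŷ ± t(1−α/2, df)·sqrt(s² + gᵀ Cov g)` with the analytic coefficient
gradient g; Monte-Carlo coverage at the true model is ~95%.  The curve
peak is located on a 0.01 Hz grid with bounded local refinement and
rounded to integer Hz for reporting; edge maxima are flagged.

The two curves are compared per frequency with a two-sided Wilcoxon
rank-sum test (midranks for ties; all-tied samples get p = 1), corrected
across frequencies with Storey q-values (λ = 0.5, π̂0 clamped to
[1/m, 1]; Benjamini–Hochberg available as fallback).  Significance flags
are placed at q < 0.005 and q < 0.001.

## Problem sizes

The test suite analyses compact cohorts (2–12 subjects per experiment,
10 trials per condition, epochs generated at 256 Hz) and uses 500-refit
coverage studies, 800–2000-replicate calibration simulations, and a
2000-condition SNR study; these sizes give stable medians and rates while
keeping a full run in tens of seconds.

## Known limitations

- The default reference curve's absolute scale rests on the peak-value
  anchoring described above.
- Electrophysiological thresholds inherit a negative bias from the
  z > 0 floor; the package reports what the estimator defines, not a
  bias-corrected threshold.
- Baseline statistics are strictly per condition (10 baseline epochs by
  default), so σ_B is noisy; pooling baselines across MDs within a
  frequency would stabilise it but is not what the procedure specifies.
- ICA-based ocular cleaning, photodiode resynchronisation and bad-channel
  interpolation are out of scope; the preprocessing hook accepts an
  external cleaner.
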