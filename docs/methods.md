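# Methods

This document describes the models and estimators implemented in
`audiomarkers`: what each computes, the parameters and their defaults, what
the synthetic generators emulate (and deliberately do not), and the numerical
choices involved.

## 1. Stimuli (`audiomarkers.stimuli`)

All stimuli are synthesized as peak-normalized sampled waveforms at a default
25 kHz rate. Presentation levels travel as metadata only; no acoustic
calibration chain exists in silico.

**FM tone.** 500 Hz carrier, sinusoidal FM at `rate_hz` (2 Hz) with peak
excursion `depth_hz` (test conditions use 0, 2, 5, 8, 10 Hz). The phase is the
exact integral of the instantaneous frequency, anchored so the FM offset is
zero at onset. A quasi-sinusoidal level modulation (`am_depth_db`, default
6 dB peak-to-trough) defeats excitation-pattern listening; its rate and phase
are spec fields so synthesis stays deterministic. 5 ms raised-cosine ramps;
`polarity` (±1) flips the waveform for polarity-alternated EEG averaging.

**IPD train.** 520 Hz carrier, 100%-depth sinusoidal AM at 40.8 Hz, interaural
carrier phase alternating between diotic and dichotic states at 6.8 Hz. The
AM/alternation ratio must be an integer (here 6) so every state transition
lands on an envelope minimum — enforced with an `AlignmentError`. In
`opposing` mode the ears shift ±`per_ear_shift_deg` (total IPD twice that); in
the `same_polarity` control both ears shift identically, leaving zero
interaural difference while matching the monaural phase discontinuities.

**ABR pip.** 3 kHz tone pip, 5 ms long with 2.5 ms raised-cosine ramps.

## 2. Synthetic data (`audiomarkers.simulate`)

All generators are phenomenological: they reproduce the *signal structure the
estimators rely on* with exact, retrievable ground truth. There is no cochlear
mechanics, no synaptic or neural membrane model, no subject fatigue or
attention dynamics.

* **Background noise** is Gaussian with a 1/f^`exponent` spectrum (pink by
  default, more EEG-like than white), RMS-normalized to `noise_sd`.
* **FMFR epochs**: `neural_gain * max(s, 0) + cm_gain * s + noise` per epoch,
  where `s` is the stimulus waveform. The half-wave-rectified term stands in
  for the aggregate phase-locked neural response; the linear term for
  pre-neural, polarity-following components (cochlear microphonic). Real
  rectification is soft and level-dependent; hard rectification is used
  because only the existence of even-order distortion at 2F matters to the
  estimator.
* **IPD recordings**: an envelope following response
  `neural_gain * cos(2π·40.8 t)` plus a binaural component modeled as a
  raised-cosine bump following every diotic↔dichotic transition, scaled by
  `binaural_gain * sensitivity(total IPD)` with a saturating logistic
  sensitivity (half point 90° total IPD, width 30°, rescaled to zero at 0°).
  Because both transition directions evoke the same response, the bump train
  is periodic at the 6.8 Hz transition rate — which is where the following
  response is measured. A literal state-times-envelope model would instead put
  the binaural fundamental at 3.4 Hz with exactly zero 6.8 Hz energy, so it is
  not used. Ground-truth amplitudes: the 6.8 Hz cosine amplitude of the bump
  train is `0.5 * binaural_gain * sensitivity`. The default 1020 Hz sampling
  rate makes the two-transition epoch exactly 300 samples (12 AM cycles), so
  epoch averaging never drifts.
* **Psychophysical observers** are Bernoulli with a logistic psychometric
  anchored so that p(`true_threshold`) equals the 2-down-1-up convergence
  point √(1/2) exactly, regardless of guess and lapse rates. FM/IPD observers
  live on a log stimulus axis (2AFC, guess 0.5); the digits observer on linear
  dB SNR with guess (1/8)⁴ (four digits, eight alternatives each).
* **Pupil sessions**: trials of 2 s baseline + 2 s digits + 2 s wait at 30 Hz.
  Evoked dilation is a raised-cosine kernel whose fractional peak grows
  linearly as SNR falls (`effort_gain * (offset + snr_max − snr)`); blinks are
  0.2 s missing-sample gaps (Poisson), plus occasional single-sample tracker
  spikes, per-block baseline drift, and white measurement noise. A bright/dark
  pair (2.5/7.5 mm) sets the light-evoked dynamic range. No pupillary
  light-reflex dynamics or arousal drift are modeled.
* **ABR epochs**: biphasic Gaussian-pair deflections (peak plus following
  trough 0.5 ms later, σ = 0.2 ms), normalized to unit peak-to-trough, at
  canonical wave I–V latencies (1.7, 2.8, 3.9, 5.1, 5.9 ms) with amplitudes
  (0.25, 0.12, 0.30, 0.15, 0.40 µV). Stimulus polarity only affects an
  optional linear pip artifact, which the two-polarity average cancels.
* **Cohorts**: two independent standard-normal latent factors per subject —
  T (temporal coding) and E (listening effort). Each standardized marker is
  `λ_T·T + λ_E·E + unique noise`, then affinely mapped to natural units (which
  preserves correlations exactly). Default loadings are calibrated so the
  population correlations with the speech outcome (loadings 0.70, 0.60) are
  0.85 for the behavioral FM threshold (which loads on *both* factors — a
  purely bottom-up FM threshold jointly consistent with the other targets does
  not exist, since 0.85² + 0.53² > 1), 0.49 for the FMFR slope (0.70 on T
  only) and 0.53 for the pupil slope (0.883 on E only). The four neural
  markers are mutually uncorrelated; remaining markers load on neither factor.

## 3. FMFR estimation (`audiomarkers.fmfr`)

`rectified_average` sums the two polarity means: `max(s,0) + max(−s,0) = |s|`,
so half-wave-rectified components add to a full-wave-rectified response —
periodic at twice the 500 Hz carrier — while linear components cancel exactly.

`heterodyne` demodulates the 1000 Hz component: DFT → zero negative
frequencies (analytic signal) → circular bin shift mapping 1000 Hz to 0 →
exponential frequency filter `exp(−|f|/B)` → inverse DFT → unwrapped, linearly
detrended phase. The 2 Hz phase amplitude (sin/cos projection) is converted to
a stimulus-frequency excursion by `rate/2`, because a depth-d stimulus carries
a phase amplitude of `2d/rate` radians at 2F.

*Filter bandwidth.* The exponential filter attenuates the modulation
sidebands and biases the recovered excursion low; for shallow modulation the
bias approaches `exp(−rate/B)`. With `B = 20 Hz` the bias at depth 2 Hz is
−3.9%, which violates the 2% recovery requirement, so the default is
`B = 60 Hz` (bias ≤ 1.4% at all tested depths while still annihilating the DC
and 4F images a full 1000 Hz away). The parameter is configurable; narrow it
for very noisy recordings where phase unwrapping needs more smoothing.

`bootstrap_fmfr` subsamples `n_draw` = 100 epochs per polarity without
replacement, `n_rep` = 1000 times; phase time series are averaged across
repetitions and the amplitude is computed from the mean phase series.

`fmfr_growth` normalizes the per-depth phase amplitudes by a caller-supplied
positive reference — the 1000 Hz spectral magnitude of the depth-0 (pure tone)
rectified average — and fits the growth sigmoid. The normalization divides a
phase amplitude (radians) by a voltage magnitude; the constant units cancel in
between-subject comparisons of the slope metric.

## 4. IPDFR estimation (`audiomarkers.ipdfr`)

The continuous recording is cut into 300 consecutive epochs of two transitions
(2/6.8 s = 294.118 ms; the nominal value is often printed as 294.3 ms) and
averaged point-wise. Amplitudes at 6.8 and 40.8 Hz are read out by exact
sin/cos projection rather than an FFT bin lookup, because the epoch's 3.4 Hz
bin grid does not contain 6.8 Hz. The IPDFR is expressed as a fraction of the
EFR. `spectral_peak` locates the dominant component in a band on a fine
frequency grid; it demeans and tiles the (periodic) epoch average 25× first —
on the raw 294 ms support, DC leakage and the negative-frequency image of a
2-cycle component bias the argmax.

## 5. ABR (`audiomarkers.abr`)

Grand average = mean of the two polarity means (linear artifacts cancel,
polarity-invariant waves survive at original amplitude); zero-phase Butterworth
band-pass 300–3000 Hz (order 2, `sosfiltfilt`); wave 1 = maximum in a 1–3 ms
window minus the minimum within 1.5 ms after it. A window-edge crest that is
not a genuine local maximum raises `NoPickError`, flagging unusable subjects
instead of scoring them zero. The zero-phase filter slightly attenuates the
narrow wave (a few percent); read-back validation is therefore performed on
the unfiltered noiseless average.

## 6. Psychophysics (`audiomarkers.psychophysics`)

**Staircases.** 2-down-1-up with geometric steps, converging on √(1/2) ≈
70.7% correct. FM track: start 75 Hz, factor 1.5 for the first 5 reversals,
then 1.2 for 7 more; IPD track: start 81°, 1.5×4 then 1.2×6. The factor in
force is the one *before* a movement's own reversal is logged (the step
producing the last coarse reversal still uses the coarse factor). Reversals
are logged at the pre-movement level; the consecutive-correct counter resets
after every level change. Run value = geometric mean of the last six
reversals. Runs repeat until the sample CV of the run values is ≤ 0.2
(minimum 3 runs, cap 6); threshold = median run value. A track that cannot
accrue its reversals within 500 trials raises `ConvergenceError`.

**Digits task.** 4 practice blocks (5 trials; target-only, 20, 9, 3 dB SNR),
then 40 test blocks of 8 trials — 3 refreshers at 20 dB plus 5 at the block
SNR, with SNRs {9, 6, 3, 0} dB shuffled independently within every cycle of
four blocks (10 blocks, 50 scored trials per SNR). The SRT is where a
maximum-likelihood logistic fit of the 200 test trials (guess (1/8)⁴, fitted
midpoint, slope, and lapse ≤ 0.1; L-BFGS-B) crosses 70.7%. Crossings below
0 dB are clamped to 0; a curve that never reaches criterion within the tested
0–20 dB range is flagged `above_range` instead of extrapolated.

## 7. Pupillometry (`audiomarkers.pupil`)

Preprocessing order: cubic-spline interpolation across missing samples (gaps
touching a trace boundary raise by default, or hold the nearest value with
`edge_mode="nearest"`), a Hampel filter (window 7, threshold 3 × 1.4826 × MAD;
a zero local MAD makes any deviation an outlier), then a centered 5-point
moving average with edge padding. Baseline = block-average of the last 500 ms
of each trial's baseline period. The per-SNR index is the peak of the
*across-trial average* fractional-change series in the digits window (not the
average of per-trial peaks, which would be noise-biased upward). Peaks are
multiplied back by the baseline and divided by the light-evoked dynamic range,
cancelling tracker gain, and regressed over difficulty = `snr_ref − snr`.

## 8. Growth metric (`audiomarkers.growth`)

A four-parameter logistic `y_min + (y_max − y_min)/(1 + exp(−k(x − x_half)))`
is least-squares fitted (bounds keep `y_min ≥ 0` and `x_half` within
`[min(x), 2·max(x)]`; deterministic initialization). Degenerate data fall back
to a flat fit flagged `flat=True` with `k = 0`; the flat fallback is also used
when it has the smaller residual. The slope metric is
`(y_max − y_min)/x_half`: large for responses that span a wide range and
saturate early. It is undefined (raises) for `x_half ≤ 0`.

## 9. Cohort statistics (`audiomarkers.cohort`)

Pairwise-complete Pearson correlations (zero-variance pairs flagged NaN);
adjusted R² = `1 − (1 − R²)(N − 1)/(N − p − 1)`; forward model building on
complete cases only, predictors entering by descending univariate R² with
ties broken by a fixed canonical order; every fit is an OLS with intercept via
statsmodels. Zero-variance or rank-deficient designs raise
`SingularDesignError` naming the offending columns. `pairwise_models` reports
all unordered two-predictor combinations. No imputation and no
multiple-comparison correction are applied.

## Numerical choices

* Spectral amplitudes use sin/cos projection (`2·|mean(x·e^{−i2πft})|`), exact
  for frequencies off the DFT grid.
* The heterodyne uses a circular spectral shift of the full analytic spectrum
  rather than time-domain mixing, making the 2F image placement exact.
* The IPD generator's 1020 Hz rate is commensurate with all stimulus rates;
  analysis functions accept any rate, but non-commensurate rates accumulate
  epoch-boundary rounding drift that attenuates the averaged 40.8 Hz
  component.
* Bootstrap draws are without replacement within repetition, matching the
  subsampling (not resampling) definition of the averaging procedure.

## Limitations

* Generators are signal-level emulations: no cochlear nonlinearity beyond
  hard rectification, no latency jitter across epochs, no 60 Hz or EOG
  artifacts, no pupil light-reflex or arousal dynamics, no lapses of attention
  beyond the stationary lapse rate.
* The latent-factor cohort model is linear-Gaussian; it reproduces a target
  correlation structure but not distributional quirks (floors, skew) of real
  marker measurements.
* The speech psychometric is fitted over only four SNR levels; the estimated
  percent-correct at the estimated SRT is therefore slightly below the
  criterion on average (≈1.5 points over many sessions), a small-sample MLE
  property rather than a bias in the protocol simulation.
* Wave-1 picking assumes a single dominant positive peak in 1–3 ms; pathologic
  morphologies (double peaks, delayed waves) are flagged, not resolved.
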