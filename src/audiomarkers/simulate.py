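"""Synthetic-data generators for every input the analysis pipeline consumes.

Each generator is a pure function of (spec, seed) and returns (or carries)
ground truth sufficient to score the downstream estimators:

* epoched EEG for the FMFR: a half-wave-rectified phase-locked neural
  component plus a polarity-flipping pre-neural (cochlear-microphonic-like)
  component plus 1/f background noise;
* continuous binaural scalp recordings with an envelope following response at
  the AM rate and a transition-locked binaural response at the IPD alternation
  rate, scaled by a saturating sensitivity function of total IPD;
* Bernoulli psychophysical observers with logistic psychometric functions
  anchored at the 70.7% (2-down-1-up convergence) point;
* pupil sessions with blinks, single-sample outliers, baseline drift, and
  SNR-dependent evoked dilation;
* ABR epochs built from biphasic (peak + following trough) deflections at
  canonical wave latencies;
* whole subject cohorts with a two-latent-factor correlation structure
  (temporal coding T, listening effort E) among the markers and the
  multi-talker speech threshold.

All components are phenomenological; there is no biophysical cochlear or
neuron model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .fmfr import EpochedResponse
from .ipdfr import ContinuousRecording
from .psychophysics import P_CONVERGENCE
from .pupil import (BASELINE_S, DIGITS_S, SAMPLE_RATE_HZ, WAIT_S, PupilSession,
                    PupilTrace)
from .stimuli import FMStimulusSpec, IPDStimulusSpec, make_abr_pip, make_fm_tone


# ---------------------------------------------------------------------------
# background noise
# ---------------------------------------------------------------------------

def powerlaw_noise(rng: np.random.Generator, shape, sample_rate_hz: float,
                   sd: float, exponent: float = 1.0) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent power spectrum, RMS-normalized.

    ``exponent`` 0 gives white noise, 1 the pink default (more realistic for
    EEG background than white).
    """
    if sd == 0:
        return np.zeros(shape)
    x = rng.standard_normal(shape)
    if exponent == 0:
        return sd * x
    n = x.shape[-1]
    X = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(X * scale, n=n, axis=-1)
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    rms = np.where(rms == 0, 1.0, rms)
    return sd * x / rms


# ---------------------------------------------------------------------------
# epoched EEG (FMFR)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EEGSimSpec:
    """Gains of the simulated EEG components.

    ``neural_gain`` scales the half-wave-rectified phase-locked component,
    ``cm_gain`` the linear polarity-flipping (cochlear-microphonic-like)
    component.  For continuous binaural recordings ``neural_gain`` scales the
    envelope following response.
    """

    neural_gain: float = 1.0
    cm_gain: float = 0.5
    noise_sd: float = 1.0
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.neural_gain < 0 or self.cm_gain < 0 or self.noise_sd < 0:
            raise InvalidSpecError("gains and noise_sd must be >= 0")


def simulate_fm_epochs(
    eeg: EEGSimSpec,
    stim: FMStimulusSpec | None = None,
    n_per_polarity: int = 200,
    seed: int | np.random.Generator | None = None,
) -> EpochedResponse:
    """Alternating-polarity epochs: neural*max(s,0) + cm*s + 1/f noise."""
    if n_per_polarity < 1:
        raise InvalidSpecError("n_per_polarity must be >= 1")
    stim = stim or FMStimulusSpec()
    rng = np.random.default_rng(eeg.seed if seed is None else seed)
    s_pos = make_fm_tone(stim if stim.polarity == 1
                         else replace(stim, polarity=1)).samples
    s_neg = -s_pos
    fs = stim.sample_rate_hz

    def epochs_for(s):
        clean = eeg.neural_gain * np.maximum(s, 0.0) + eeg.cm_gain * s
        noise = powerlaw_noise(rng, (n_per_polarity, len(s)), fs,
                               eeg.noise_sd, eeg.noise_exponent)
        return clean[None, :] + noise

    return EpochedResponse(epochs_for(s_pos), epochs_for(s_neg), fs,
                           stimulus_spec=stim)


# ---------------------------------------------------------------------------
# continuous binaural recording (IPDFR)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinauralSensitivity:
    """Saturating (logistic) sensitivity to total IPD, zero at 0 degrees."""

    half_deg: float = 90.0   # total IPD at half saturation
    scale_deg: float = 30.0  # logistic width

    def __call__(self, total_ipd_deg: float) -> float:
        l0 = 1.0 / (1.0 + math.exp(self.half_deg / self.scale_deg))
        l = 1.0 / (1.0 + math.exp(-(total_ipd_deg - self.half_deg) / self.scale_deg))
        return (l - l0) / (1.0 - l0)


def simulate_ipd_recording(
    eeg: EEGSimSpec,
    stim: IPDStimulusSpec | None = None,
    binaural_gain: float = 1.0,
    sensitivity: BinauralSensitivity | None = None,
    sample_rate_hz: float = 1020.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[ContinuousRecording, dict]:
    """Scalp-like recording with EFR and transition-locked IPD components.

    The envelope following response is a sinusoid at the AM rate with
    amplitude ``eeg.neural_gain``.  The binaural component is a raised-cosine
    response bump following every diotic<->dichotic transition; since both
    transition directions evoke the same response, it is periodic at the
    transition rate (6.8 Hz), which is where the following response is
    measured.  Its amplitude is ``binaural_gain * sensitivity(total IPD)``,
    zero at 0 degrees and in the same-polarity control.

    The default 1020 Hz sampling rate is commensurate with the stimulus rates
    (exactly 300 samples per two-transition epoch, 12 AM cycles), so epoching
    never drifts across the recording; scalp content lives below 50 Hz.
    """
    stim = stim or IPDStimulusSpec()
    sens_fn = sensitivity or BinauralSensitivity()
    if stim.duration_s * stim.alt_rate_hz < 4:
        raise InvalidSpecError("recording must span several alternation cycles")
    rng = np.random.default_rng(eeg.seed if seed is None else seed)
    fs = sample_rate_hz
    n = int(round(stim.duration_s * fs))
    t = np.arange(n) / fs
    total_ipd = (0.0 if stim.control_mode == "same_polarity"
                 else 2.0 * stim.per_ear_shift_deg)
    sens = sens_fn(total_ipd)
    efr = eeg.neural_gain * np.cos(2 * np.pi * stim.am_rate_hz * t)
    # zero at every transition instant (t = k / alt_rate), peaking in between
    bump = 0.5 * (1.0 - np.cos(2 * np.pi * stim.alt_rate_hz * t))
    x = efr + binaural_gain * sens * bump
    x = x + powerlaw_noise(rng, n, fs, eeg.noise_sd, eeg.noise_exponent)
    truth = {
        "sensitivity": sens,
        "ipdfr_amp": 0.5 * binaural_gain * sens,  # 6.8 Hz cosine amplitude
        "efr_amp": eeg.neural_gain,
        "total_ipd_deg": total_ipd,
    }
    return ContinuousRecording(x, fs, stimulus_spec=stim), truth


# ---------------------------------------------------------------------------
# psychophysical observers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObserverSpec:
    """Logistic Bernoulli observer anchored at the 70.7% point.

    ``true_threshold`` is the stimulus magnitude at which the observer's
    percent correct equals the 2-down-1-up convergence point sqrt(1/2).
    ``log_axis`` selects a logistic in log magnitude (FM excursion, IPD:
    geometric staircases) vs in linear units (speech dB SNR, where LARGER
    SNR is easier).
    """

    true_threshold: float
    slope: float = 6.0
    guess_rate: float = 0.5
    lapse_rate: float = 0.0
    log_axis: bool = True
    harder_when_larger: bool = False  # True for thresholds where larger=harder

    def __post_init__(self):
        if not 0 <= self.guess_rate < 1:
            raise InvalidSpecError("guess rate must lie in [0, 1)")
        if not 0 <= self.lapse_rate <= 0.1:
            raise InvalidSpecError("lapse rate must lie in [0, 0.1]")
        q = (P_CONVERGENCE - self.guess_rate) / (1 - self.guess_rate - self.lapse_rate)
        if not 0 < q < 1:
            raise InvalidSpecError("70.7% point unreachable with these rates")
        if self.true_threshold <= 0 and self.log_axis:
            raise InvalidSpecError("log-axis threshold must be positive")


@dataclass(frozen=True)
class Observer:
    """Callable observer: ``obs(magnitude, rng) -> bool``."""

    spec: ObserverSpec

    def _axis(self, magnitude):
        x = np.log(magnitude) if self.spec.log_axis else np.asarray(magnitude,
                                                                    float)
        return -x if self.spec.harder_when_larger else x

    def prob(self, magnitude) -> float | np.ndarray:
        s = self.spec
        q = (P_CONVERGENCE - s.guess_rate) / (1 - s.guess_rate - s.lapse_rate)
        u0 = self._axis(s.true_threshold) - math.log(q / (1 - q)) / s.slope
        f = 1.0 / (1.0 + np.exp(-s.slope * (self._axis(magnitude) - u0)))
        return s.guess_rate + (1 - s.guess_rate - s.lapse_rate) * f

    def __call__(self, magnitude, rng: np.random.Generator) -> bool:
        return bool(rng.random() < self.prob(magnitude))


def simulate_observer_response(obs: Observer, magnitude,
                               rng: np.random.Generator) -> bool:
    """One Bernoulli trial at the given stimulus magnitude."""
    return obs(magnitude, rng)


#: chance level of the 4-digit all-correct report (8 alternatives per digit)
DIGITS_GUESS_RATE = (1.0 / 8.0) ** 4


def make_fm_observer(threshold_hz: float = 3.0, slope: float = 6.0,
                     lapse: float = 0.02) -> Observer:
    """2AFC FM-detection observer on a log excursion-depth axis."""
    return Observer(ObserverSpec(threshold_hz, slope, guess_rate=0.5,
                                 lapse_rate=lapse, log_axis=True))


def make_ipd_observer(threshold_deg: float = 12.0, slope: float = 6.0,
                      lapse: float = 0.02) -> Observer:
    """2AFC IPD-detection observer on a log per-ear-shift axis."""
    return Observer(ObserverSpec(threshold_deg, slope, guess_rate=0.5,
                                 lapse_rate=lapse, log_axis=True))


def make_speech_observer(threshold_db: float = 3.0, slope: float = 0.6,
                         lapse: float = 0.01) -> Observer:
    """Digits-task observer over linear dB SNR (larger SNR easier).

    ``slope`` is per dB; chance is the all-four-digits guess rate (~0).
    """
    return Observer(ObserverSpec(threshold_db, slope,
                                 guess_rate=DIGITS_GUESS_RATE,
                                 lapse_rate=lapse, log_axis=False))


# ---------------------------------------------------------------------------
# pupillometry sessions
# ---------------------------------------------------------------------------

def simulate_pupil_session(
    snr_schedule_db=None,
    trials_per_block: int = 5,
    effort_gain: float = 0.005,
    effort_offset_db: float = 2.0,
    blink_rate_hz: float = 0.1,
    spike_prob: float = 0.1,
    noise_sd: float = 0.01,
    baseline_mm: float = 4.5,
    drift_sd: float = 0.02,
    bright_mm: float = 2.5,
    dark_mm: float = 7.5,
    seed: int | np.random.Generator = 0,
) -> PupilSession:
    """Simulate a pupillometry session over the digits-task SNR blocks.

    Each trial is 2 s baseline + 2 s digits + 2 s wait at 30 Hz.  The evoked
    fractional dilation peaks at ``effort_gain * (offset + snr_max - snr)``,
    growing linearly as SNR falls.  Blinks appear as missing-sample gaps at
    ``blink_rate_hz``; occasional single-sample spikes emulate tracker
    glitches.  A bright/dark light-calibration trace sets the subject's
    dynamic range.
    """
    rng = np.random.default_rng(seed)
    if snr_schedule_db is None:
        snr_schedule_db = [9.0, 6.0, 3.0, 0.0] * 5  # 20 blocks
    snr_schedule_db = list(snr_schedule_db)
    fs = SAMPLE_RATE_HZ
    n_trial = int(round((BASELINE_S + DIGITS_S + WAIT_S) * fs))
    t = np.arange(n_trial) / fs
    digits_on, digits_off = BASELINE_S, BASELINE_S + DIGITS_S
    kernel = np.where(
        (t >= digits_on) & (t < digits_off),
        0.5 * (1 - np.cos(2 * np.pi * (t - digits_on) / DIGITS_S)),
        0.0,
    )
    snr_max = max(snr_schedule_db)
    amp_for = {snr: effort_gain * (effort_offset_db + snr_max - snr)
               for snr in set(snr_schedule_db)}

    trials = []
    for block, snr in enumerate(snr_schedule_db):
        block_base = baseline_mm * (1.0 + drift_sd * rng.standard_normal())
        for _ in range(trials_per_block):
            d = block_base * (1.0 + amp_for[snr] * kernel)
            d = d + noise_sd * rng.standard_normal(n_trial)
            missing = np.zeros(n_trial, dtype=bool)
            n_blinks = rng.poisson(blink_rate_hz * n_trial / fs)
            for _ in range(n_blinks):
                gap = max(2, int(round(0.2 * fs)))
                start = rng.integers(1, n_trial - gap - 1)
                missing[start : start + gap] = True
            if rng.random() < spike_prob:
                i = int(rng.integers(1, n_trial - 1))
                if not missing[i]:
                    d[i] += 0.5 * baseline_mm * rng.choice([-1.0, 1.0])
            trials.append(PupilTrace(d, missing, snr, block))

    light_range = dark_mm - bright_mm
    truth = {
        "peak_frac_by_snr": dict(sorted(amp_for.items())),
        "baseline_mm": baseline_mm,
        "light_range_mm": light_range,
    }
    return PupilSession(trials, light_range, truth)


# ---------------------------------------------------------------------------
# ABR epochs
# ---------------------------------------------------------------------------

#: canonical wave I-V peak latencies (ms) and peak-to-trough amplitudes (uV)
DEFAULT_ABR_LATENCIES_MS = (1.7, 2.8, 3.9, 5.1, 5.9)
DEFAULT_ABR_AMPLITUDES_UV = (0.25, 0.12, 0.30, 0.15, 0.40)


def _abr_kernel(n: int, fs: float, latency_ms: float, sigma_ms: float = 0.2,
                trough_delay_ms: float = 0.5) -> np.ndarray:
    """Biphasic deflection (Gaussian peak, following trough), unit ptp."""
    t_ms = np.arange(n) / fs * 1e3
    g = np.exp(-0.5 * ((t_ms - latency_ms) / sigma_ms) ** 2)
    g -= np.exp(-0.5 * ((t_ms - latency_ms - trough_delay_ms) / sigma_ms) ** 2)
    return g / np.ptp(g)


def simulate_abr(
    wave_amplitudes=DEFAULT_ABR_AMPLITUDES_UV,
    wave_latencies_ms=DEFAULT_ABR_LATENCIES_MS,
    noise_sd: float = 0.5,
    n_per_polarity: int = 1000,
    seed: int | np.random.Generator = 0,
    sample_rate_hz: float = 25_000.0,
    epoch_s: float = 0.010,
    artifact_gain: float = 0.0,
    noise_exponent: float = 1.0,
) -> EpochedResponse:
    """Epochs of Gaussian-windowed wave I-V deflections plus noise.

    Stimulus polarity affects only a small linear artifact term (the tone pip
    scaled by ``artifact_gain``), which cancels in the two-polarity average.
    """
    lats = np.asarray(wave_latencies_ms, dtype=float)
    amps = np.asarray(wave_amplitudes, dtype=float)
    if np.any(np.diff(lats) <= 0):
        raise InvalidSpecError("wave latencies must be increasing")
    rng = np.random.default_rng(seed)
    fs = sample_rate_hz
    n = int(round(epoch_s * fs))
    clean = np.zeros(n)
    for amp, lat in zip(amps, lats):
        clean += amp * _abr_kernel(n, fs, lat)
    pip = make_abr_pip(sample_rate_hz=fs).samples
    artifact = np.zeros(n)
    artifact[: min(n, len(pip))] = pip[: min(n, len(pip))]

    def epochs_for(pol):
        noise = powerlaw_noise(rng, (n_per_polarity, n), fs, noise_sd,
                               noise_exponent)
        return clean[None, :] + pol * artifact_gain * artifact[None, :] + noise

    return EpochedResponse(epochs_for(+1), epochs_for(-1), fs)


# ---------------------------------------------------------------------------
# subject cohorts
# ---------------------------------------------------------------------------

#: marker -> (loading on T, loading on E); all markers standardized.
#: Calibrated so the population marker-outcome correlations reproduce the
#: calibration targets: r(fm_thr, speech)=0.85, r(fmfr, speech)=0.49,
#: r(pupil, speech)=0.53, with the four neural markers mutually uncorrelated.
#: The behavioral FM threshold loads on BOTH factors (it carries top-down
#: variance beyond the FMFR).
DEFAULT_LOADINGS = {
    "fm_thr": (0.85, 0.425),
    "ipd_thr": (0.0, 0.0),
    "fmfr_slope": (0.70, 0.0),
    "ipdfr_slope": (0.0, 0.0),
    "pupil_slope": (0.0, 0.8833333333333333),
    "abr_w1": (0.0, 0.0),
    "ehf_thr": (0.0, 0.0),
}

#: marker -> (location, scale) on natural units
DEFAULT_MARKER_SCALES = {
    "fm_thr": (5.0, 2.0),          # Hz
    "ipd_thr": (12.0, 5.0),        # deg (per ear)
    "fmfr_slope": (0.08, 0.03),    # 1/Hz
    "ipdfr_slope": (0.004, 0.0015),  # 1/deg
    "pupil_slope": (0.012, 0.005),   # 1/dB
    "abr_w1": (0.25, 0.07),        # uV
    "ehf_thr": (20.0, 10.0),       # dB HL
    "speech_thr": (2.42, 1.8),     # dB SNR
}


@dataclass(frozen=True)
class CohortSpec:
    """Two-latent-factor cohort model: T (temporal coding) and E (effort)."""

    n_subjects: int = 23
    loadings: dict = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    outcome_loadings: tuple = (0.70, 0.60)  # (c_T, c_E) for speech_thr
    marker_scales: dict = field(default_factory=lambda: dict(DEFAULT_MARKER_SCALES))
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 4:
            raise InvalidSpecError("need at least 4 subjects")
        for name, (lt, le) in self.loadings.items():
            if lt * lt + le * le >= 1.0:
                raise InvalidSpecError(
                    f"loadings for {name} imply |r| >= 1 (norm >= 1)"
                )
        ct, ce = self.outcome_loadings
        if ct * ct + ce * ce >= 1.0:
            raise InvalidSpecError("outcome loadings imply |r| >= 1")


def cohort_ground_truth(spec: CohortSpec) -> pd.DataFrame:
    """Population correlation matrix implied by the latent-factor model."""
    names = list(spec.loadings) + ["speech_thr"]
    lam = {n: np.asarray(v, float) for n, v in spec.loadings.items()}
    lam["speech_thr"] = np.asarray(spec.outcome_loadings, float)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r.loc[a, b] = r.loc[b, a] = float(lam[a] @ lam[b])
    return r


def simulate_cohort(spec: CohortSpec | None = None,
                    seed: int | np.random.Generator | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a subject table; returns (table, population correlation matrix).

    Latents T, E are independent standard normals per subject; each marker is
    loading.T*T + loading.E*E + unique noise, standardized, then mapped to its
    natural units by an affine scale (so the correlation structure is exact).
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_subjects
    t_lat = rng.standard_normal(n)
    e_lat = rng.standard_normal(n)

    def realize(name, lt, le):
        noise_sd = math.sqrt(1.0 - lt * lt - le * le)
        z = lt * t_lat + le * e_lat + noise_sd * rng.standard_normal(n)
        loc, scale = spec.marker_scales[name]
        return loc + scale * z

    data = {"subject": [f"S{i + 1:02d}" for i in range(n)]}
    for name, (lt, le) in spec.loadings.items():
        data[name] = realize(name, lt, le)
    ct, ce = spec.outcome_loadings
    data["speech_thr"] = realize("speech_thr", ct, ce)
    return pd.DataFrame(data), cohort_ground_truth(spec)
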