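"""Deterministic synthesis of the acoustic stimuli used throughout the battery.

Three stimulus families are produced as sampled waveforms:

* a slow sinusoidal-FM tone (500 Hz carrier, 2 Hz rate, excursion depths up to
  10 Hz) with a shallow quasi-sinusoidal amplitude modulation that defeats
  cochlear excitation-pattern cues;
* a binaural interaural-phase-difference (IPD) train: a 520 Hz carrier,
  100%-depth AM at 40.8 Hz, whose carrier phase alternates between diotic and
  dichotic states at 6.8 Hz, every transition landing on an AM envelope
  minimum;
* a brief 3 kHz tone pip used to evoke auditory brainstem responses.

Waveform amplitude is normalized full scale; presentation levels (dB SPL/SL)
travel as metadata only, since no acoustic calibration chain exists in silico.
Default sample rate is 25 kHz, the acquisition rate at which all downstream
analysis operates.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml
from scipy.io import wavfile

from .errors import AlignmentError, InvalidSpecError

DEFAULT_SAMPLE_RATE_HZ = 25_000.0


@dataclass(frozen=True)
class Waveform:
    """A mono sampled waveform (voltage-like amplitude units)."""

    samples: np.ndarray
    sample_rate_hz: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(samples)):
            raise InvalidSpecError("waveform contains non-finite samples")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate_hz


@dataclass(frozen=True)
class StereoWaveform:
    """Two-channel sampled waveform (left, right)."""

    left: np.ndarray
    right: np.ndarray
    sample_rate_hz: float

    def __post_init__(self):
        left = np.asarray(self.left, dtype=float)
        right = np.asarray(self.right, dtype=float)
        if len(left) != len(right):
            raise InvalidSpecError("channel lengths differ")
        if not (np.all(np.isfinite(left)) and np.all(np.isfinite(right))):
            raise InvalidSpecError("waveform contains non-finite samples")
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.left)) / self.sample_rate_hz


@dataclass(frozen=True)
class FMStimulusSpec:
    """Sinusoidal FM tone with quasi-sinusoidal AM.

    ``depth_hz`` is the peak instantaneous-frequency excursion; the testing
    conditions use {0, 2, 5, 8, 10} Hz (0 is a pure tone).  The quasi-AM is a
    level modulation with ``am_depth_db`` peak-to-trough range at a rate drawn
    per trial from 1-3 Hz with random starting phase; the drawn values live in
    the spec so synthesis itself stays deterministic.
    """

    carrier_hz: float = 500.0
    rate_hz: float = 2.0
    depth_hz: float = 10.0
    duration_s: float = 1.0
    ramp_s: float = 0.005
    polarity: int = 1
    am_rate_hz: float = 2.0
    am_depth_db: float = 6.0
    am_phase_rad: float = 0.0
    level_db_sl: float = 55.0  # metadata only
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self):
        if self.depth_hz < 0:
            raise InvalidSpecError("depth_hz must be >= 0")
        if self.depth_hz >= self.carrier_hz:
            raise InvalidSpecError("depth_hz must be below the carrier frequency")
        if self.sample_rate_hz <= 4 * self.carrier_hz:
            raise InvalidSpecError("sample_rate_hz must exceed 4x carrier")
        if self.polarity not in (1, -1):
            raise InvalidSpecError("polarity must be +1 or -1")
        if self.duration_s <= 0 or self.ramp_s < 0:
            raise InvalidSpecError("duration/ramp must be positive")
        if self.ramp_s > self.duration_s / 2:
            raise InvalidSpecError("ramps exceed half the stimulus duration")


@dataclass(frozen=True)
class IPDStimulusSpec:
    """AM tone whose interaural carrier phase alternates diotic/dichotic.

    ``per_ear_shift_deg`` is applied to each ear; in ``opposing`` mode the two
    ears shift with opposite sign (total IPD = 2x per-ear shift), in
    ``same_polarity`` mode they share sign (control: zero interaural
    difference).  ``am_rate_hz``/``alt_rate_hz`` must be an integer so every
    state transition lands on an envelope minimum.
    """

    carrier_hz: float = 520.0
    am_rate_hz: float = 40.8
    alt_rate_hz: float = 6.8
    per_ear_shift_deg: float = 90.0
    duration_s: float = 2 / 6.8 * 300  # 300 epochs of two transitions each
    level_db_spl: float = 85.0  # metadata only
    control_mode: str = "opposing"
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self):
        ratio = self.am_rate_hz / self.alt_rate_hz
        if abs(ratio - round(ratio)) > 1e-9:
            raise AlignmentError(
                "am_rate_hz must be an integer multiple of alt_rate_hz so AM "
                "minima coincide with phase transitions"
            )
        if not 0 <= self.per_ear_shift_deg <= 180:
            raise InvalidSpecError("per_ear_shift_deg must lie in [0, 180]")
        if self.control_mode not in ("opposing", "same_polarity"):
            raise InvalidSpecError("control_mode must be opposing|same_polarity")
        if self.duration_s <= 0:
            raise InvalidSpecError("duration_s must be positive")


def _raised_cosine_ramps(n: int, ramp_s: float, fs: float) -> np.ndarray:
    """Unit gate with raised-cosine on/off ramps of ``ramp_s`` seconds."""
    gate = np.ones(n)
    n_ramp = int(round(ramp_s * fs))
    if n_ramp > 0:
        # 0 at the first sample, 1 one sample past the ramp
        r = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        gate[:n_ramp] = r
        gate[-n_ramp:] = r[::-1]
    return gate


def make_fm_tone(spec: FMStimulusSpec) -> Waveform:
    """Synthesize the FM tone.

    Instantaneous frequency is ``carrier + depth*sin(2*pi*rate*t)``; the
    quasi-AM multiplies the amplitude by ``10**(g(t)/20)`` where ``g`` swings
    over ``am_depth_db`` peak-to-trough, scaled so the post-AM peak is 1.
    """
    fs = spec.sample_rate_hz
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    # phase = 2*pi * integral of instantaneous frequency
    phase = 2 * np.pi * spec.carrier_hz * t
    if spec.depth_hz > 0:
        phase -= (spec.depth_hz / spec.rate_hz) * (
            np.cos(2 * np.pi * spec.rate_hz * t) - 1.0
        )
    s = np.sin(phase)
    # level modulation, peak-normalized: ranges [-am_depth_db, 0] dB
    g_db = 0.5 * spec.am_depth_db * (
        np.sin(2 * np.pi * spec.am_rate_hz * t + spec.am_phase_rad) - 1.0
    )
    s = s * 10.0 ** (g_db / 20.0)
    s *= _raised_cosine_ramps(n, spec.ramp_s, fs)
    return Waveform(spec.polarity * s, fs)


def make_ipd_train(spec: IPDStimulusSpec) -> StereoWaveform:
    """Synthesize the binaural IPD alternation train.

    The carrier phase switches between the diotic state and the dichotic state
    at ``alt_rate_hz``; transitions occur at envelope minima of the 100%-depth
    sinusoidal AM.
    """
    fs = spec.sample_rate_hz
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    env = 0.5 * (1 - np.cos(2 * np.pi * spec.am_rate_hz * t))  # minima at k/am_rate
    # state: 0 (diotic) on even transition intervals, 1 (dichotic) on odd
    state = (np.floor(t * spec.alt_rate_hz) % 2).astype(float)
    shift = np.deg2rad(spec.per_ear_shift_deg)
    phase_l = shift * state
    phase_r = (shift if spec.control_mode == "same_polarity" else -shift) * state
    base = 2 * np.pi * spec.carrier_hz * t
    left = env * np.sin(base + phase_l)
    right = env * np.sin(base + phase_r)
    return StereoWaveform(left, right, fs)


def make_abr_pip(
    freq_hz: float = 3000.0,
    duration_s: float = 0.005,
    ramp_s: float = 0.0025,
    polarity: int = 1,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
) -> Waveform:
    """Raised-cosine-gated tone pip used to evoke the ABR.

    The presentation cadence (11.1/s) and level (105 dB SPL) are epoch-
    simulator metadata, not baked into the waveform.
    """
    if ramp_s > duration_s / 2:
        raise InvalidSpecError("ramp longer than half the pip duration")
    if polarity not in (1, -1):
        raise InvalidSpecError("polarity must be +1 or -1")
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    s = np.sin(2 * np.pi * freq_hz * t)
    s *= _raised_cosine_ramps(n, ramp_s, sample_rate_hz)
    return Waveform(polarity * s, sample_rate_hz)


def write_wav(path, wave: Waveform | StereoWaveform, subtype: str = "float32"):
    """Write a waveform as RIFF WAV (float32 or int16) for audition/debugging."""
    if isinstance(wave, StereoWaveform):
        data = np.stack([wave.left, wave.right], axis=1)
    else:
        data = wave.samples
    if subtype == "int16":
        peak = np.max(np.abs(data)) or 1.0
        data = np.round(data / peak * 32767).astype(np.int16)
    else:
        data = data.astype(np.float32)
    wavfile.write(str(path), int(wave.sample_rate_hz), data)


def write_spec_config(path, spec):
    """Serialize a stimulus spec as a flat key-value YAML config."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(spec), fh, sort_keys=True)
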