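"""Auditory brainstem response filtering and wave-1 amplitude measurement.

The averaged ABR is band-passed 300 Hz - 3 kHz (zero phase) and wave 1 is
measured as the amplitude of the first major positive peak minus the following
trough.  Picking is algorithmic (the field's manual marking replaced by fixed
search windows): peak = maximum in a 1-3 ms window, trough = minimum within a
configurable horizon after the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import InvalidSpecError, NoPickError
from .stimuli import Waveform


@dataclass(frozen=True)
class WavePick:
    peak_latency_ms: float
    peak_amp: float
    trough_latency_ms: float
    trough_amp: float

    @property
    def wave1_amp(self) -> float:
        return self.peak_amp - self.trough_amp


def polarity_mean_average(resp) -> Waveform:
    """Grand average over both polarities (mean of the two polarity means).

    Linear, polarity-flipping artifacts cancel; the polarity-invariant evoked
    waves survive at their original amplitude.
    """
    avg = 0.5 * (resp.epochs_pos.mean(axis=0) + resp.epochs_neg.mean(axis=0))
    return Waveform(avg, resp.sample_rate_hz)


def bandpass_abr(avg: Waveform, lo_hz: float = 300.0, hi_hz: float = 3000.0,
                 order: int = 2) -> Waveform:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    fs = avg.sample_rate_hz
    if not 0 < lo_hz < hi_hz < fs / 2:
        raise InvalidSpecError("invalid band edges for the sample rate")
    sos = butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs, output="sos")
    return Waveform(sosfiltfilt(sos, avg.samples), fs)


def pick_wave1(
    filtered: Waveform,
    search_window_ms: tuple[float, float] = (1.0, 3.0),
    trough_horizon_ms: float = 1.5,
) -> WavePick:
    """Peak-to-following-trough measurement of wave 1.

    Raises :class:`NoPickError` when the window holds no local maximum (e.g.
    flat or monotone segments), so unusable subjects are flagged rather than
    silently scored zero.
    """
    fs = filtered.sample_rate_hz
    x = filtered.samples
    i_lo = int(round(search_window_ms[0] * 1e-3 * fs))
    i_hi = int(round(search_window_ms[1] * 1e-3 * fs))
    if not 0 <= i_lo < i_hi <= len(x):
        raise InvalidSpecError("search window outside the epoch")
    seg = x[i_lo:i_hi]
    if np.ptp(seg) == 0:
        raise NoPickError("flat segment in the wave-1 search window")
    i_peak = i_lo + int(np.argmax(seg))
    # require a genuine local maximum, not a window-edge crest
    if i_peak in (i_lo, i_lo + len(seg) - 1):
        interior = (
            0 < i_peak < len(x) - 1
            and x[i_peak] >= x[i_peak - 1]
            and x[i_peak] >= x[i_peak + 1]
        )
        if not interior:
            raise NoPickError("no local maximum inside the search window")
    j_hi = min(len(x), i_peak + 1 + int(round(trough_horizon_ms * 1e-3 * fs)))
    if j_hi <= i_peak + 1:
        raise NoPickError("no samples after the peak for the trough search")
    tseg = x[i_peak + 1 : j_hi]
    i_trough = i_peak + 1 + int(np.argmin(tseg))
    return WavePick(
        peak_latency_ms=i_peak / fs * 1e3,
        peak_amp=float(x[i_peak]),
        trough_latency_ms=i_trough / fs * 1e3,
        trough_amp=float(x[i_trough]),
    )
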