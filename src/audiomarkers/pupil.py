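"""Pupillometry preprocessing and the SNR-dependent listening-effort metric.

Trials are 30 Hz pupil-diameter traces spanning a 2 s pre-trial baseline, 2 s
of digit presentation and a 2 s wait.  Preprocessing (in this order): cubic-
spline interpolation across blinks/missing periods, a Hampel filter for
outlier samples, and a centered 5-point moving average.  The per-trial
fractional change is (diameter - baseline)/baseline with the baseline taken as
the block-average of the last 500 ms of the baseline window; the per-SNR
effort index is the peak of the across-trial average fractional-change series
during the digits window.  Peaks are expressed as a fraction of the subject's
light-evoked dynamic range (bright vs dark screen) and the growth of the
normalized peak over task difficulty is reduced to the min-max/halfmax slope
metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import InvalidSpecError, NormalizationError
from .growth import GrowthCurve, SigmoidFit, fit_sigmoid

SAMPLE_RATE_HZ = 30.0
BASELINE_S = 2.0
DIGITS_S = 2.0
WAIT_S = 2.0
BASELINE_WINDOW_S = 0.5  # last 500 ms of the baseline period


@dataclass(frozen=True)
class PupilTrace:
    """One trial's pupil-diameter trace with blink mask and markers."""

    diameter: np.ndarray
    missing: np.ndarray
    snr_db: float
    block: int = 0
    sample_rate_hz: float = SAMPLE_RATE_HZ
    baseline_s: float = BASELINE_S
    digits_s: float = DIGITS_S

    def __post_init__(self):
        d = np.asarray(self.diameter, dtype=float)
        m = np.asarray(self.missing, dtype=bool)
        if d.shape != m.shape:
            raise InvalidSpecError("diameter and missing mask differ in length")
        object.__setattr__(self, "diameter", d)
        object.__setattr__(self, "missing", m)

    @property
    def baseline_slice(self) -> slice:
        return slice(0, int(round(self.baseline_s * self.sample_rate_hz)))

    @property
    def digits_slice(self) -> slice:
        i0 = int(round(self.baseline_s * self.sample_rate_hz))
        return slice(i0, i0 + int(round(self.digits_s * self.sample_rate_hz)))


@dataclass(frozen=True)
class PupilSession:
    """A full session: trials plus the light (bright/dark) calibration."""

    trials: list
    light_range: float
    ground_truth: dict | None = None


def interpolate_gaps(x: np.ndarray, missing: np.ndarray,
                     edge_mode: str = "raise") -> np.ndarray:
    """Fill missing samples with a cubic spline through the valid samples."""
    x = np.asarray(x, dtype=float)
    missing = np.asarray(missing, dtype=bool)
    if not missing.any():
        return x.copy()
    valid = ~missing
    if valid.sum() < 4:
        raise InvalidSpecError("too few valid samples to spline-interpolate")
    if missing[0] or missing[-1]:
        if edge_mode == "raise":
            raise InvalidSpecError(
                "gap touches the trace boundary; set edge_mode='nearest'"
            )
        if edge_mode != "nearest":
            raise InvalidSpecError("edge_mode must be 'raise' or 'nearest'")
    idx = np.arange(len(x))
    spline = CubicSpline(idx[valid], x[valid], extrapolate=False)
    out = x.copy()
    out[missing] = spline(idx[missing])
    if missing[0] or missing[-1]:  # edges: hold the nearest valid value
        first, last = idx[valid][0], idx[valid][-1]
        out[:first] = x[first]
        out[last + 1:] = x[last]
    return out


def hampel_filter(x: np.ndarray, window: int = 7, n_sigmas: float = 3.0
                  ) -> np.ndarray:
    """Replace samples deviating > n_sigmas scaled MADs from the local median.

    ``window`` is the full window length (center sample plus 3 on each side by
    default); edges use the available shorter windows.
    """
    if window % 2 == 0 or window < 3:
        raise InvalidSpecError("window must be odd and >= 3")
    x = np.asarray(x, dtype=float)
    half = window // 2
    out = x.copy()
    k = 1.4826  # scaled-MAD consistency constant for Gaussian data
    for i in range(len(x)):
        seg = x[max(0, i - half): i + half + 1]
        med = np.median(seg)
        mad = np.median(np.abs(seg - med))
        # a zero MAD (at least half the window identical) makes any deviation
        # from the local median an outlier, so the comparison stays strict
        if abs(x[i] - med) > n_sigmas * k * mad:
            out[i] = med
    return out


def moving_average(x: np.ndarray, n_points: int = 5) -> np.ndarray:
    """Centered moving average with edge-value padding."""
    half = n_points // 2
    padded = np.pad(np.asarray(x, dtype=float), half, mode="edge")
    return np.convolve(padded, np.ones(n_points) / n_points, mode="valid")


def preprocess(trace: PupilTrace, hampel_window: int = 7,
               hampel_sigmas: float = 3.0, smooth_points: int = 5,
               edge_mode: str = "raise") -> PupilTrace:
    """Spline-fill blinks, Hampel-filter outliers, then 5-point smooth."""
    x = interpolate_gaps(trace.diameter, trace.missing, edge_mode=edge_mode)
    x = hampel_filter(x, window=hampel_window, n_sigmas=hampel_sigmas)
    x = moving_average(x, n_points=smooth_points)
    return PupilTrace(x, np.zeros_like(trace.missing, dtype=bool), trace.snr_db,
                      trace.block, trace.sample_rate_hz, trace.baseline_s,
                      trace.digits_s)


def _trial_baseline_mean(trace: PupilTrace) -> float:
    """Mean of the last 500 ms of the trial's baseline period."""
    b = trace.diameter[trace.baseline_slice]
    n = int(round(BASELINE_WINDOW_S * trace.sample_rate_hz))
    return float(np.mean(b[-n:]))


def fractional_change(
    trials: list, baseline_per: str = "block"
) -> pd.DataFrame:
    """Per-SNR peak fractional change (and absolute dilation) across trials.

    The baseline is the block-average of the per-trial last-500 ms baseline
    means by default (``baseline_per='trial'`` uses each trial's own).  The
    per-SNR value is the peak of the across-trial AVERAGE fractional series in
    the digits window, not the average of per-trial peaks.

    Returns a frame indexed by SNR with columns ``peak_frac`` (dimensionless),
    ``baseline`` and ``peak_dilation`` (diameter units).
    """
    if baseline_per not in ("block", "trial"):
        raise InvalidSpecError("baseline_per must be 'block' or 'trial'")
    base_by_block: dict[int, float] = {}
    if baseline_per == "block":
        blocks: dict[int, list[float]] = {}
        for tr in trials:
            blocks.setdefault(tr.block, []).append(_trial_baseline_mean(tr))
        base_by_block = {b: float(np.mean(v)) for b, v in blocks.items()}
        if any(v <= 0 for v in base_by_block.values()):
            raise NormalizationError("non-positive baseline pupil diameter")

    series: dict[float, list[np.ndarray]] = {}
    bases: dict[float, list[float]] = {}
    for tr in trials:
        base = (base_by_block[tr.block] if baseline_per == "block"
                else _trial_baseline_mean(tr))
        if base <= 0:
            raise NormalizationError("non-positive baseline pupil diameter")
        frac = (tr.diameter[tr.digits_slice] - base) / base
        series.setdefault(tr.snr_db, []).append(frac)
        bases.setdefault(tr.snr_db, []).append(base)

    rows = []
    for snr in sorted(series):
        mean_series = np.mean(np.vstack(series[snr]), axis=0)
        peak = float(np.max(mean_series))
        base = float(np.mean(bases[snr]))
        rows.append((snr, peak, base, peak * base))
    return pd.DataFrame(rows, columns=["snr_db", "peak_frac", "baseline",
                                       "peak_dilation"]).set_index("snr_db")


def pupil_growth(
    peaks: pd.DataFrame, light_range: float, snr_ref_db: float | None = None
) -> tuple[GrowthCurve, SigmoidFit]:
    """Growth of light-normalized peak dilation over task difficulty.

    Difficulty is ``snr_ref - snr`` (oriented so effort grows as SNR falls;
    the reference defaults to the easiest tested SNR).  Peaks are divided by
    the light-evoked dynamic range, cancelling pupillometer gain.
    """
    if light_range <= 0 or not np.isfinite(light_range):
        raise NormalizationError("light-evoked dynamic range must be positive")
    snrs = np.asarray(sorted(peaks.index, reverse=True), dtype=float)
    if len(snrs) < 3:
        raise InvalidSpecError("need >=3 SNR conditions")
    ref = float(snrs[0]) if snr_ref_db is None else snr_ref_db
    x = ref - snrs
    y = peaks.loc[snrs, "peak_dilation"].to_numpy() / light_range
    curve = GrowthCurve(x, y, "pupil")
    return curve, fit_sigmoid(curve)
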