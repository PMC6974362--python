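"""Sigmoidal growth-curve fitting and the min-max/halfmax slope metric.

Normalized response growth functions (FMFR amplitude vs FM depth, IPDFR vs
total IPD, pupil dilation vs task difficulty) are reduced to a single slope
index per subject: a four-parameter logistic is fitted and the dynamic range
(y_max - y_min) is divided by the stimulus magnitude at the halfway point
(x_half).  Subjects whose response saturates early (small x_half) and spans a
wide range get large values.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings
from typing import Sequence

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import InvalidSpecError


@dataclass(frozen=True)
class GrowthCurve:
    """Normalized response amplitude sampled over a stimulus-magnitude axis."""

    x: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if len(x) != len(y) or len(x) < 3:
            raise InvalidSpecError("growth curve needs >=3 matched points")
        if not np.all(np.diff(x) > 0):
            raise InvalidSpecError("x axis must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise InvalidSpecError("y values must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class SigmoidFit:
    y_min: float
    y_max: float
    x_half: float
    k: float
    flat: bool = False  # degenerate-data fallback (k forced to 0)

    @property
    def min_max(self) -> float:
        return self.y_max - self.y_min

    @property
    def slope_metric(self) -> float:
        return slope_metric(self)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.flat or self.k == 0:
            return np.full_like(x, 0.5 * (self.y_min + self.y_max))
        return self.y_min + (self.y_max - self.y_min) / (
            1 + np.exp(-self.k * (x - self.x_half))
        )


def _logistic4(x, y_min, y_range, x_half, k):
    return y_min + y_range / (1 + np.exp(-k * (x - x_half)))


def fit_sigmoid(curve: GrowthCurve) -> SigmoidFit:
    """Least-squares 4-parameter logistic fit with deterministic initialization.

    Bounds keep y_min >= 0 and x_half within [min(x), 2*max(x)].  Degenerate
    (flat or non-finite) data fall back to a flat fit flagged with k = 0; the
    flat fallback is also used whenever it has the smaller residual norm.
    """
    x, y = curve.x, curve.y
    flat_fit = SigmoidFit(float(np.mean(y)), float(np.mean(y)), float(np.median(x)),
                          0.0, flat=True)
    y_range0 = float(np.max(y) - np.min(y))
    if y_range0 <= 0:
        return flat_fit

    span = float(x[-1] - x[0])
    k0 = 4.0 * (y[-1] - y[0]) / (y_range0 * span) if span > 0 else 1.0
    k0 = max(k0, 1e-3)
    p0 = [max(float(np.min(y)), 0.0), y_range0, float(np.median(x)), k0]
    lower = [0.0, 0.0, float(x[0]), 1e-6]
    upper = [max(float(np.max(y)), 1e-12), np.inf, 2.0 * float(x[-1]), np.inf]
    p0 = np.clip(p0, lower, upper)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _logistic4, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
            )
    except (RuntimeError, ValueError):
        return flat_fit
    fit = SigmoidFit(float(popt[0]), float(popt[0] + popt[1]), float(popt[2]),
                     float(popt[3]))
    resid = float(np.sum((fit.predict(x) - y) ** 2))
    resid_flat = float(np.sum((flat_fit.predict(x) - y) ** 2))
    if not np.isfinite(resid) or resid > resid_flat:
        return flat_fit
    return fit


def slope_metric(fit: SigmoidFit) -> float:
    """(y_max - y_min) / x_half, the min-max/halfmax slope index (units 1/x)."""
    if fit.x_half <= 0:
        raise InvalidSpecError("slope metric undefined for x_half <= 0")
    return (fit.y_max - fit.y_min) / fit.x_half


def fit_growth(x: Sequence[float], y: Sequence[float], label: str = "") -> SigmoidFit:
    """Convenience wrapper: build the curve and fit in one call."""
    return fit_sigmoid(GrowthCurve(np.asarray(x, float), np.asarray(y, float), label))
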