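"""Pupillometry preprocessing and the effort growth metric."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from audiomarkers.errors import InvalidSpecError, NormalizationError
from audiomarkers.pupil import (
    BASELINE_S,
    DIGITS_S,
    SAMPLE_RATE_HZ,
    WAIT_S,
    PupilTrace,
    fractional_change,
    hampel_filter,
    interpolate_gaps,
    moving_average,
    preprocess,
    pupil_growth,
)
from audiomarkers.simulate import simulate_pupil_session

N_TRIAL = int(round((BASELINE_S + DIGITS_S + WAIT_S) * SAMPLE_RATE_HZ))


def synthetic_trace(snr=0.0, block=0, baseline=4.0, peak_frac=0.05):
    """Clean trace: flat baseline, raised-cosine dilation during digits."""
    t = np.arange(N_TRIAL) / SAMPLE_RATE_HZ
    kernel = np.where(
        (t >= BASELINE_S) & (t < BASELINE_S + DIGITS_S),
        0.5 * (1 - np.cos(2 * np.pi * (t - BASELINE_S) / DIGITS_S)),
        0.0,
    )
    d = baseline * (1.0 + peak_frac * kernel)
    return PupilTrace(d, np.zeros(N_TRIAL, dtype=bool), snr, block)


class TestInterpolation:
    def test_spline_is_exact_on_smooth_data(self):
        x = np.linspace(0.0, 2.0, 60) ** 2  # cubic spline reproduces quadratics
        missing = np.zeros(60, dtype=bool)
        missing[20:26] = True
        out = interpolate_gaps(x, missing)
        assert np.allclose(out, x, atol=1e-6)

    def test_no_gap_returns_copy(self):
        x = np.arange(10.0)
        out = interpolate_gaps(x, np.zeros(10, dtype=bool))
        assert np.array_equal(out, x)
        assert out is not x

    def test_edge_gap_raises_by_default(self):
        x = np.arange(10.0)
        missing = np.zeros(10, dtype=bool)
        missing[0] = True
        with pytest.raises(InvalidSpecError):
            interpolate_gaps(x, missing)

    def test_edge_gap_nearest_mode_holds_value(self):
        x = np.arange(10.0)
        missing = np.zeros(10, dtype=bool)
        missing[:3] = True
        out = interpolate_gaps(x, missing, edge_mode="nearest")
        assert np.allclose(out[:3], x[3])

    def test_too_few_valid_samples(self):
        with pytest.raises(InvalidSpecError):
            interpolate_gaps(np.arange(5.0), np.array([0, 1, 1, 1, 0],
                                                      dtype=bool))


class TestHampel:
    def test_single_spike_replaced_by_local_median(self):
        x = np.ones(21)
        x[10] = 50.0
        out = hampel_filter(x)
        assert out[10] == 1.0
        assert np.allclose(np.delete(out, 10), 1.0)

    def test_clean_slowly_varying_data_unchanged(self):
        x = np.sin(np.linspace(0, np.pi, 50))
        assert np.allclose(hampel_filter(x), x)

    def test_even_window_rejected(self):
        with pytest.raises(InvalidSpecError):
            hampel_filter(np.ones(10), window=6)


class TestSmoothing:
    @given(st.floats(min_value=-10, max_value=10))
    def test_constant_preserved(self, c):
        x = np.full(30, c)
        assert np.allclose(moving_average(x), c)

    def test_length_preserved(self):
        assert len(moving_average(np.arange(17.0))) == 17


class TestPreprocess:
    def test_pipeline_restores_clean_trace(self):
        clean = synthetic_trace()
        d = clean.diameter.copy()
        missing = np.zeros(N_TRIAL, dtype=bool)
        missing[40:46] = True          # a blink
        d[100] += 3.0                  # a tracker spike
        dirty = PupilTrace(d, missing, 0.0)
        out = preprocess(dirty)
        assert np.allclose(out.diameter, moving_average(clean.diameter),
                           atol=0.02)


class TestFractionalChange:
    def test_readback_of_constructed_peaks(self):
        trials = [synthetic_trace(snr, block=b, peak_frac=frac)
                  for b, (snr, frac) in enumerate([(9.0, 0.01), (6.0, 0.03),
                                                   (3.0, 0.05)])
                  for _ in range(4)]
        peaks = fractional_change(trials)
        assert peaks.loc[9.0, "peak_frac"] == pytest.approx(0.01, rel=1e-6)
        assert peaks.loc[3.0, "peak_frac"] == pytest.approx(0.05, rel=1e-6)
        assert peaks.loc[3.0, "peak_dilation"] == pytest.approx(0.05 * 4.0,
                                                                rel=1e-6)

    def test_affine_gain_invariance_of_fraction(self):
        gain = 2.5
        trials = [synthetic_trace(snr, block=i)
                  for i, snr in enumerate([9.0, 6.0, 3.0])]
        scaled = [PupilTrace(gain * tr.diameter, tr.missing, tr.snr_db,
                             tr.block) for tr in trials]
        p1 = fractional_change(trials)
        p2 = fractional_change(scaled)
        assert np.allclose(p1["peak_frac"], p2["peak_frac"])
        assert np.allclose(gain * p1["peak_dilation"], p2["peak_dilation"])

    def test_nonpositive_baseline_rejected(self):
        tr = synthetic_trace()
        bad = PupilTrace(tr.diameter - 10.0, tr.missing, 0.0)
        with pytest.raises(NormalizationError):
            fractional_change([bad])

    def test_invalid_baseline_mode(self):
        with pytest.raises(InvalidSpecError):
            fractional_change([synthetic_trace()], baseline_per="session")


class TestGrowthMetric:
    def make_peaks(self):
        trials = [synthetic_trace(snr, block=i, peak_frac=frac)
                  for i, (snr, frac) in enumerate(
                      [(9.0, 0.01), (6.0, 0.025), (3.0, 0.04), (0.0, 0.055)])]
        return fractional_change(trials)

    def test_difficulty_axis_is_reference_minus_snr(self):
        curve, _ = pupil_growth(self.make_peaks(), light_range=5.0)
        assert np.allclose(curve.x, [0.0, 3.0, 6.0, 9.0])

    def test_light_normalization_cancels_tracker_gain(self):
        peaks = self.make_peaks()
        _, fit1 = pupil_growth(peaks, light_range=5.0)
        scaled = peaks.copy()
        scaled["peak_dilation"] *= 2.0
        _, fit2 = pupil_growth(scaled, light_range=10.0)
        assert fit1.slope_metric == pytest.approx(fit2.slope_metric, rel=1e-6)

    def test_light_range_must_be_positive(self):
        with pytest.raises(NormalizationError):
            pupil_growth(self.make_peaks(), light_range=0.0)

    def test_needs_three_snr_conditions(self):
        peaks = self.make_peaks().iloc[:2]
        with pytest.raises(InvalidSpecError):
            pupil_growth(peaks, light_range=5.0)


class TestSimulatedSession:
    def test_full_pipeline_recovers_ground_truth(self):
        session = simulate_pupil_session(seed=0)
        clean = [preprocess(tr, edge_mode="nearest") for tr in session.trials]
        peaks = fractional_change(clean)
        truth = session.ground_truth["peak_frac_by_snr"]
        for snr, frac in truth.items():
            assert peaks.loc[snr, "peak_frac"] == pytest.approx(frac, abs=0.01)
        curve, fit = pupil_growth(peaks, session.light_range)
        assert np.all(np.diff(curve.y) > 0)  # effort grows with difficulty
        assert fit.slope_metric > 0
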