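"""Staircase engine, run collection, and the digits-task threshold fit."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from audiomarkers import psychophysics as psy
from audiomarkers.errors import ConvergenceError, InvalidSpecError
from audiomarkers.psychophysics import (
    FM_STAIRCASE,
    IPD_STAIRCASE,
    P_CONVERGENCE,
    StaircaseConfig,
    StaircaseState,
    collect_runs,
    geometric_mean,
    run_speech_session,
    run_staircase,
    speech_threshold,
    staircase_step,
)
from audiomarkers.simulate import make_fm_observer, make_speech_observer


class TestStaircaseStep:
    def test_two_correct_divide_one_wrong_multiply(self):
        state = StaircaseState(FM_STAIRCASE)
        staircase_step(state, True)
        assert state.level == 75.0  # one correct: no movement yet
        staircase_step(state, True)
        assert state.level == pytest.approx(75.0 / 1.5)
        staircase_step(state, False)
        assert state.level == pytest.approx(75.0)

    def test_consecutive_counter_resets_after_movement(self):
        state = StaircaseState(FM_STAIRCASE)
        for _ in range(4):
            staircase_step(state, True)
        # four corrects = two down-steps, not three
        assert state.level == pytest.approx(75.0 / 1.5**2)

    def test_reversal_logged_at_pre_movement_level(self):
        state = StaircaseState(FM_STAIRCASE)
        staircase_step(state, True)
        staircase_step(state, True)   # down to 50
        staircase_step(state, False)  # up: first reversal, logged at 50
        assert state.reversal_levels == [pytest.approx(50.0)]

    def test_first_movement_is_not_a_reversal(self):
        state = StaircaseState(FM_STAIRCASE)
        staircase_step(state, False)
        assert state.reversal_levels == []

    def test_factor_switches_after_coarse_reversal_quota(self):
        # strict alternation: wrong, then two corrects, repeated.  Every
        # movement after the first is a reversal; the step that produces the
        # 5th reversal still uses the coarse factor, the 6th uses the fine one.
        state = StaircaseState(FM_STAIRCASE)
        ratios = []
        outcomes = [False] + [True, True, False] * 4
        for correct in outcomes:
            before = state.level
            staircase_step(state, correct)
            if state.level != before:
                ratios.append(max(state.level, before) / min(state.level, before))
        # 9 movements: up (no reversal), then down/up alternation = 8 reversals
        assert len(state.reversal_levels) == 8
        assert len(ratios) == 9
        assert ratios[:6] == [pytest.approx(1.5)] * 6  # through the 5th reversal
        assert ratios[6:] == [pytest.approx(1.2)] * 3  # fine steps thereafter

    def test_level_floor_enforced(self):
        cfg = StaircaseConfig(initial_level=1e-6)
        state = StaircaseState(cfg)
        staircase_step(state, True)
        staircase_step(state, True)
        assert state.level == cfg.level_floor

    def test_config_validation(self):
        with pytest.raises(InvalidSpecError):
            StaircaseConfig(initial_level=-1.0)
        with pytest.raises(InvalidSpecError):
            StaircaseConfig(initial_level=75.0, coarse_factor=1.0)
        with pytest.raises(InvalidSpecError):
            StaircaseConfig(initial_level=75.0, fine_reversals=3)


class TestRunValue:
    def test_geometric_mean_of_alternating_reversals(self):
        assert geometric_mean([4, 1, 4, 1, 4, 1]) == pytest.approx(2.0)

    @given(st.floats(min_value=0.1, max_value=100.0),
           st.lists(st.floats(min_value=0.1, max_value=100.0), min_size=2,
                    max_size=8))
    def test_geometric_mean_scale_equivariance(self, c, values):
        assert geometric_mean([c * v for v in values]) == pytest.approx(
            c * geometric_mean(values), rel=1e-9
        )

    def test_run_value_uses_last_six_reversals(self):
        obs = make_fm_observer(3.0, 6.0)
        trace = run_staircase(FM_STAIRCASE, obs, seed=0)
        assert len(trace.reversal_levels) == FM_STAIRCASE.total_reversals
        assert trace.run_value == pytest.approx(
            geometric_mean(trace.reversal_levels[-6:])
        )

    def test_always_correct_observer_never_reverses(self):
        with pytest.raises(ConvergenceError):
            run_staircase(FM_STAIRCASE, lambda level, rng: True)

    def test_ipd_track_starts_at_81_degrees(self):
        assert IPD_STAIRCASE.initial_level == 81.0
        assert IPD_STAIRCASE.total_reversals == 10


class TestRunCollection:
    def stub_runs(self, monkeypatch, values):
        seq = iter(values)

        def fake(cfg, observer, seed=0):
            class T:
                run_value = next(seq)
            return T()

        monkeypatch.setattr(psy, "run_staircase", fake)

    def test_identical_runs_stop_at_minimum_of_three(self, monkeypatch):
        self.stub_runs(monkeypatch, [2.0, 2.0, 2.0, 99.0])
        result = collect_runs(FM_STAIRCASE, None)
        assert result.n_runs == 3
        assert result.cv == 0.0
        assert result.threshold == 2.0

    def test_variable_runs_stop_at_cap_of_six(self, monkeypatch):
        self.stub_runs(monkeypatch, [1.0, 10.0, 1.0, 10.0, 1.0, 10.0, 1.0])
        result = collect_runs(FM_STAIRCASE, None)
        assert result.n_runs == 6
        assert result.cv > 0.2
        assert result.threshold == pytest.approx(np.median([1, 10, 1, 10, 1, 10]))

    def test_cv_is_sample_cv_of_run_values(self, monkeypatch):
        vals = [2.0, 2.2, 2.4]
        self.stub_runs(monkeypatch, vals)
        result = collect_runs(FM_STAIRCASE, None)
        assert result.cv == pytest.approx(
            np.std(vals, ddof=1) / np.mean(vals)
        )

    def test_threshold_is_median_of_run_values(self):
        obs = make_fm_observer(3.0, 6.0)
        result = collect_runs(FM_STAIRCASE, obs, seed=0)
        assert 3 <= result.n_runs <= 6
        assert result.threshold == pytest.approx(np.median(result.run_values))


class TestSpeechSession:
    def test_session_structure(self):
        trials = run_speech_session(make_speech_observer(3.0), seed=0)
        assert len(trials) == 340
        counts = trials["phase"].value_counts()
        assert counts["practice"] == 20
        assert counts["refresher"] == 120
        assert counts["test"] == 200

    def test_each_snr_tested_in_ten_blocks(self):
        trials = run_speech_session(make_speech_observer(3.0), seed=0)
        test = trials[trials["phase"] == "test"]
        blocks_per_snr = test.groupby("snr_db")["block"].nunique()
        assert set(blocks_per_snr.index) == {0.0, 3.0, 6.0, 9.0}
        assert (blocks_per_snr == 10).all()

    def test_blocks_hold_three_refreshers_and_five_tests(self):
        trials = run_speech_session(make_speech_observer(3.0), seed=1)
        test_blocks = trials[trials["phase"] != "practice"]
        for _, block in test_blocks.groupby("block"):
            phases = block["phase"].value_counts()
            assert phases["refresher"] == 3
            assert phases["test"] == 5
            assert (block[block["phase"] == "refresher"]["snr_db"] == 20.0).all()
            assert block[block["phase"] == "test"]["snr_db"].nunique() == 1

    def test_snrs_cycle_in_shuffled_blocks_of_four(self):
        trials = run_speech_session(make_speech_observer(3.0), seed=2)
        test = trials[trials["phase"] == "test"]
        block_snr = test.groupby("block")["snr_db"].first().to_numpy()
        for i in range(0, 40, 4):
            assert set(block_snr[i : i + 4]) == {0.0, 3.0, 6.0, 9.0}


class TestSpeechThreshold:
    def test_recovers_known_threshold(self):
        obs = make_speech_observer(3.0, 0.6)
        trials = run_speech_session(obs, seed=0)
        result = speech_threshold(trials)
        assert not result.above_range
        assert result.srt_db == pytest.approx(3.0, abs=0.5)

    def test_ceiling_observer_clamps_to_zero(self):
        obs = make_speech_observer(-20.0, 0.6)
        trials = run_speech_session(obs, seed=0)
        result = speech_threshold(trials)
        assert result.srt_db == 0.0
        assert not result.above_range

    def test_poor_observer_flagged_above_range(self):
        obs = make_speech_observer(30.0, 0.6)
        trials = run_speech_session(obs, seed=0)
        result = speech_threshold(trials)
        assert result.above_range
        assert result.srt_db is None

    def test_requires_enough_scored_trials(self):
        obs = make_speech_observer(3.0)
        trials = run_speech_session(obs, seed=0).head(40)
        with pytest.raises(InvalidSpecError):
            speech_threshold(trials)

    def test_convergence_point_is_sqrt_half(self):
        assert P_CONVERGENCE == pytest.approx(math.sqrt(0.5))
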