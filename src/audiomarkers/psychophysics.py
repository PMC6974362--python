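"""Transformed up-down staircases and the multi-talker digits protocol.

The adaptive tracks are 2-down-1-up: the stimulus magnitude is divided by the
current step factor after two consecutive correct responses and multiplied by
it after any error, converging on the 70.7%-correct point (sqrt(1/2)) of the
psychometric function.  Steps are geometric with a coarse factor of 1.5 for an
initial block of reversals and a fine factor of 1.2 thereafter; a run ends
when the configured reversal count has accrued and its value is the geometric
mean of the last six reversal levels.  Runs are repeated (3 minimum, 6 cap)
until the coefficient of variation of the run values drops to 0.2; the
threshold is the median run value.

The speech task is a 4-digit report against two competing talkers.  A session
is 4 practice blocks then 40 test blocks of 8 trials (3 refreshers at 20 dB
SNR, 5 at the block SNR; SNRs 9/6/3/0 dB shuffled per cycle of four blocks).
A trial is correct only if all four digits match.  The speech reception
threshold (SRT) is where a maximum-likelihood logistic fit of the test trials
crosses 70.7% correct; thresholds better than 0 dB SNR are marked 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import ConvergenceError, InvalidSpecError

P_CONVERGENCE = math.sqrt(0.5)  # 2-down-1-up equilibrium, ~0.7071


# ---------------------------------------------------------------------------
# staircase engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaircaseConfig:
    initial_level: float
    coarse_factor: float = 1.5
    fine_factor: float = 1.2
    coarse_reversals: int = 5
    fine_reversals: int = 7
    threshold_reversals: int = 6
    level_floor: float = 1e-6
    max_trials: int = 500

    def __post_init__(self):
        if self.coarse_factor <= 1 or self.fine_factor <= 1:
            raise InvalidSpecError("step factors must exceed 1")
        if self.fine_reversals < self.threshold_reversals:
            raise InvalidSpecError("fine_reversals must cover threshold_reversals")
        if self.initial_level <= 0 or self.level_floor <= 0:
            raise InvalidSpecError("levels must be positive")

    @property
    def total_reversals(self) -> int:
        return self.coarse_reversals + self.fine_reversals


#: FM excursion-depth track: start 75 Hz, 1.5x for 5 reversals then 1.2x for 7
FM_STAIRCASE = StaircaseConfig(initial_level=75.0, coarse_reversals=5,
                               fine_reversals=7)
#: per-ear IPD track: start 81 deg, 1.5x for 4 reversals then 1.2x for 6
IPD_STAIRCASE = StaircaseConfig(initial_level=81.0, coarse_reversals=4,
                                fine_reversals=6)


@dataclass
class StaircaseState:
    """Mutable bookkeeping for one adaptive run."""

    cfg: StaircaseConfig
    level: float = field(init=False)
    n_correct_in_row: int = field(default=0, init=False)
    last_direction: int = field(default=0, init=False)  # -1 down, +1 up
    reversal_levels: list = field(default_factory=list, init=False)
    trials: list = field(default_factory=list, init=False)  # (level, correct, reversal)

    def __post_init__(self):
        self.level = self.cfg.initial_level

    @property
    def done(self) -> bool:
        return len(self.reversal_levels) >= self.cfg.total_reversals

    @property
    def current_factor(self) -> float:
        if len(self.reversal_levels) < self.cfg.coarse_reversals:
            return self.cfg.coarse_factor
        return self.cfg.fine_factor


def staircase_step(state: StaircaseState, correct: bool) -> StaircaseState:
    """Apply one trial outcome: 2-down-1-up with geometric steps.

    The consecutive-correct counter resets after every level change; a
    reversal is logged (at the pre-movement level) whenever the movement
    direction flips.
    """
    level_before = state.level
    direction = 0
    if correct:
        state.n_correct_in_row += 1
        if state.n_correct_in_row >= 2:
            direction = -1
            state.n_correct_in_row = 0
    else:
        direction = +1
        state.n_correct_in_row = 0

    reversal = False
    if direction != 0:
        # factor is fixed before this movement's reversal (if any) is logged:
        # the step that produces the 5th reversal still uses the coarse factor
        factor = state.current_factor
        if state.last_direction != 0 and direction != state.last_direction:
            reversal = True
            state.reversal_levels.append(level_before)
        new = level_before * (factor if direction > 0 else 1.0 / factor)
        state.level = max(new, state.cfg.level_floor)
        state.last_direction = direction
    state.trials.append((level_before, bool(correct), reversal))
    return state


@dataclass(frozen=True)
class StaircaseTrace:
    trials: pd.DataFrame          # level, correct, reversal
    reversal_levels: np.ndarray
    run_value: float              # geometric mean of the last six reversals


def geometric_mean(values) -> float:
    values = np.asarray(values, dtype=float)
    return float(np.exp(np.mean(np.log(values))))


def run_staircase(cfg: StaircaseConfig, observer, seed=0) -> StaircaseTrace:
    """Simulate trials until the reversal quota is met.

    ``observer`` is called as ``observer(level, rng) -> bool``.
    """
    rng = np.random.default_rng(seed)
    state = StaircaseState(cfg)
    while not state.done:
        if len(state.trials) >= cfg.max_trials:
            raise ConvergenceError(
                f"staircase did not accrue {cfg.total_reversals} reversals "
                f"within {cfg.max_trials} trials"
            )
        staircase_step(state, observer(state.level, rng))
    reversals = np.asarray(state.reversal_levels)
    run_value = geometric_mean(reversals[-cfg.threshold_reversals:])
    trials = pd.DataFrame(state.trials, columns=["level", "correct", "reversal"])
    return StaircaseTrace(trials, reversals, run_value)


@dataclass(frozen=True)
class RunSetResult:
    run_values: np.ndarray
    cv: float
    threshold: float  # median of the run values

    @property
    def n_runs(self) -> int:
        return len(self.run_values)


def collect_runs(
    cfg: StaircaseConfig,
    observer,
    seed=0,
    min_runs: int = 3,
    max_runs: int = 6,
    cv_criterion: float = 0.2,
) -> RunSetResult:
    """Collect runs until CV <= criterion (>=3 runs) or the 6-run cap."""
    rng = np.random.default_rng(seed)
    run_values: list[float] = []
    while True:
        run_values.append(run_staircase(cfg, observer, rng).run_value)
        if len(run_values) >= min_runs:
            vals = np.asarray(run_values)
            cv = float(np.std(vals, ddof=1) / np.mean(vals))
            if cv <= cv_criterion or len(run_values) >= max_runs:
                return RunSetResult(vals, cv, float(np.median(vals)))


# ---------------------------------------------------------------------------
# multi-talker digits protocol
# ---------------------------------------------------------------------------

#: SNR label for target-only practice trials (no competing talkers)
TARGET_ONLY = math.inf

SRT_CRITERION = P_CONVERGENCE  # 70.7% correct point defines the SRT


@dataclass(frozen=True)
class SpeechProtocol:
    practice_snrs_db: tuple = (TARGET_ONLY, 20.0, 9.0, 3.0)
    practice_trials_per_block: int = 5
    n_test_blocks: int = 40
    refresher_trials: int = 3
    refresher_snr_db: float = 20.0
    test_trials_per_block: int = 5
    snr_cycle_db: tuple = (9.0, 6.0, 3.0, 0.0)


@dataclass(frozen=True)
class SpeechResult:
    percent_correct: pd.Series   # by test SNR
    srt_db: float | None         # None when flagged above range
    above_range: bool
    fit_params: dict


def run_speech_session(observer, seed=0,
                       protocol: SpeechProtocol = SpeechProtocol()) -> pd.DataFrame:
    """Simulate a full session; returns the trial ledger.

    Columns: block, trial, snr_db, phase (practice|refresher|test), correct.
    Block SNRs follow the protocol cycle, shuffled independently within each
    cycle of four blocks.
    """
    rng = np.random.default_rng(seed)
    rows = []
    block = 0
    for snr in protocol.practice_snrs_db:
        for trial in range(protocol.practice_trials_per_block):
            rows.append((block, trial, snr, "practice", observer(snr, rng)))
        block += 1
    cycle = list(protocol.snr_cycle_db)
    test_snrs: list[float] = []
    while len(test_snrs) < protocol.n_test_blocks:
        order = rng.permutation(len(cycle))
        test_snrs.extend(cycle[i] for i in order)
    for snr in test_snrs[: protocol.n_test_blocks]:
        trial = 0
        for _ in range(protocol.refresher_trials):
            rows.append((block, trial, protocol.refresher_snr_db, "refresher",
                         observer(protocol.refresher_snr_db, rng)))
            trial += 1
        for _ in range(protocol.test_trials_per_block):
            rows.append((block, trial, snr, "test", observer(snr, rng)))
            trial += 1
        block += 1
    return pd.DataFrame(rows, columns=["block", "trial", "snr_db", "phase",
                                       "correct"])


def _logistic_p(snr, mid, slope, guess, lapse):
    f = 1.0 / (1.0 + np.exp(-slope * (snr - mid)))
    return guess + (1.0 - guess - lapse) * f


def speech_threshold(
    trials: pd.DataFrame,
    guess_rate: float = (1.0 / 8.0) ** 4,
    criterion: float = SRT_CRITERION,
    snr_range_db: tuple[float, float] = (0.0, 20.0),
    include_refreshers: bool = False,
) -> SpeechResult:
    """Estimate the SRT from the trial ledger.

    A logistic psychometric (chance ``guess_rate`` to 100% minus a fitted
    lapse) is fitted by maximizing the Bernoulli likelihood over individual
    test trials; refreshers are logged but excluded by default.  The SRT is
    the fitted curve's crossing of the criterion; crossings below 0 dB are
    clamped to 0 and a curve that never reaches criterion within the tested
    range is flagged rather than numbered.
    """
    phases = ["test", "refresher"] if include_refreshers else ["test"]
    sub = trials[trials["phase"].isin(phases)]
    snr = sub["snr_db"].to_numpy(dtype=float)
    y = sub["correct"].to_numpy(dtype=float)
    by_snr = sub.groupby("snr_db")["correct"].agg(["mean", "size"])
    if (by_snr["size"] >= 20).sum() < 2:
        raise InvalidSpecError("need >=2 SNR levels with >=20 scored trials")

    def nll(params):
        mid, slope, lapse = params
        p = _logistic_p(snr, mid, slope, guess_rate, lapse)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

    x0 = np.array([float(np.median(snr)), 0.5, 0.01])
    res = minimize(nll, x0, method="L-BFGS-B",
                   bounds=[(-30.0, 40.0), (0.01, 10.0), (0.0, 0.1)])
    mid, slope, lapse = res.x
    f_star = (criterion - guess_rate) / (1.0 - guess_rate - lapse)
    pc = by_snr["mean"] * 100.0
    if f_star >= 1.0:
        srt, above = None, True
    else:
        crossing = mid + math.log(f_star / (1.0 - f_star)) / slope
        p_at_top = _logistic_p(snr_range_db[1], mid, slope, guess_rate, lapse)
        if crossing > snr_range_db[1] or p_at_top < criterion:
            srt, above = None, True
        else:
            srt, above = max(crossing, snr_range_db[0]), False
    return SpeechResult(
        percent_correct=pc,
        srt_db=srt,
        above_range=above,
        fit_params={"mid_db": float(mid), "slope": float(slope),
                    "lapse": float(lapse), "guess": guess_rate},
    )
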