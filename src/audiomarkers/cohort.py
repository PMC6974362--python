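"""Cohort-level statistics: correlations and the forward multivariable model.

One row per subject of all markers plus the multi-talker speech threshold
(outcome).  Analyses: Pearson pairwise correlations (pairwise-complete),
forward OLS regression where predictors enter in decreasing order of
univariate R² with the adjusted R² reported at each step, and all two-variable
combinations to probe order effects.  Model building uses complete cases only
and the N used is reported; no imputation, no multiple-testing correction
(univariate p-values are plain t-tests on n-2 df).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InvalidSpecError, SingularDesignError

#: canonical order used to break ties in univariate-R² ranking
CANONICAL_PREDICTOR_ORDER = (
    "pupil_slope", "fmfr_slope", "abr_w1", "ipdfr_slope", "ehf_thr",
    "fm_thr", "ipd_thr",
)


@dataclass(frozen=True)
class ModelFit:
    predictors: tuple
    r2: float
    adj_r2: float
    n: int

    @property
    def p(self) -> int:
        return len(self.predictors)


def pearson_matrix(table: pd.DataFrame, columns=None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p, pairwise-complete observations.

    Zero-variance pairs are flagged NaN rather than raising.
    """
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = table[[a, b]].dropna()
            if len(pair) < 3 or pair[a].std() == 0 or pair[b].std() == 0:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 - (1 - R²)(N - 1)/(N - p - 1)."""
    if not 0 <= r2 <= 1:
        raise InvalidSpecError("R² must lie in [0, 1]")
    if n <= p + 1:
        raise InvalidSpecError("need n > p + 1 for the adjustment")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _check_design(x: pd.DataFrame):
    bad = [c for c in x.columns if x[c].std() == 0]
    if bad:
        raise SingularDesignError(bad)
    design = sm.add_constant(x.to_numpy(dtype=float))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError(list(x.columns))


def _ols_r2(table: pd.DataFrame, outcome: str, predictors) -> float:
    x = table[list(predictors)]
    _check_design(x)
    model = sm.OLS(table[outcome].to_numpy(dtype=float),
                   sm.add_constant(x.to_numpy(dtype=float))).fit()
    return float(model.rsquared)


def univariate_r2(table: pd.DataFrame, outcome: str, predictors
                  ) -> pd.Series:
    """Univariate OLS R² of each predictor against the outcome."""
    table = table[[outcome, *predictors]].dropna()
    return pd.Series({p: _ols_r2(table, outcome, [p]) for p in predictors})


def forward_model(table: pd.DataFrame, outcome: str = "speech_thr",
                  predictors=None) -> list[ModelFit]:
    """Cumulative OLS fits with predictors entering by descending univariate R².

    Complete-case rows only; ties in the ranking are broken by the canonical
    predictor order.  Returns one :class:`ModelFit` per step.
    """
    if predictors is None:
        predictors = [c for c in CANONICAL_PREDICTOR_ORDER if c in table.columns]
    table = table[[outcome, *predictors]].dropna()
    n = len(table)
    if n < 4:
        raise InvalidSpecError("need >=4 complete-case rows")
    uni = univariate_r2(table, outcome, predictors)
    canon = {name: i for i, name in enumerate(CANONICAL_PREDICTOR_ORDER)}
    ranked = sorted(predictors,
                    key=lambda c: (-uni[c], canon.get(c, len(canon)), c))
    fits = []
    for step in range(1, len(ranked) + 1):
        chosen = tuple(ranked[:step])
        r2 = _ols_r2(table, outcome, chosen)
        fits.append(ModelFit(chosen, r2, adjusted_r2(r2, n, step), n))
    return fits


def pairwise_models(table: pd.DataFrame, outcome: str = "speech_thr",
                    predictors=None) -> pd.DataFrame:
    """Adjusted R² of every unordered two-predictor combination."""
    if predictors is None:
        predictors = [c for c in CANONICAL_PREDICTOR_ORDER if c in table.columns]
    table = table[[outcome, *predictors]].dropna()
    n = len(table)
    if n < 4:
        raise InvalidSpecError("need >=4 complete-case rows")
    rows = []
    for i, a in enumerate(predictors):
        for b in predictors[i + 1:]:
            r2 = _ols_r2(table, outcome, [a, b])
            rows.append((a, b, r2, adjusted_r2(r2, n, 2), n))
    return pd.DataFrame(rows, columns=["predictor_a", "predictor_b", "r2",
                                       "adj_r2", "n"])
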