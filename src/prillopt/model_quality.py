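"""Predictability and accuracy statistics for fitted response models.

Predictability is the coefficient of determination on the percentage scale,
R2 = (1 - SS_res/SS_tot) x 100.  Accuracy is judged by the regression F
statistic derived from R2 and caller-supplied degrees of freedom, compared
against the upper 5% critical value of the F distribution.  Degrees of
freedom are never derived internally: different modelling tools count
coefficients differently, so they are inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, DomainError

#: models above this predictability threshold are reported as reasonably predictable
PREDICTABILITY_THRESHOLD_PCT = 70.0


@dataclass(frozen=True)
class ModelQuality:
    r2_percent: float
    f_calc: float
    df1: int
    df2: int
    f_crit: float
    significant: bool
    f_capped: bool = False

    @property
    def reasonably_predictable(self) -> bool:
        return self.r2_percent > PREDICTABILITY_THRESHOLD_PCT

    def as_dict(self) -> dict:
        d = asdict(self)
        d["reasonably_predictable"] = self.reasonably_predictable
        return d


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, percent scale.

    May be negative for predictors worse than the observed mean.  No
    standardization is applied internally; both sequences must share units.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise DomainError(f"observed and predicted must be equal-length 1-D sequences, got {y.shape} and {yhat.shape}")
    if y.size < 2:
        raise DomainError(f"need at least 2 observations, got {y.size}")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateInputError("observed sequence is constant; R2 undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    return (1.0 - ss_res / ss_tot) * 100.0


def f_from_r2(r2_percent: float, df1: int, df2: int) -> float:
    """Regression F statistic (R2/v1) / ((1-R2)/v2), with R2 as a fraction."""
    if df1 < 1 or df2 < 1:
        raise DomainError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    if not 0.0 <= r2_percent < 100.0:
        if r2_percent >= 100.0:
            raise DomainError("R2 = 100% implies an infinite F statistic")
        raise DomainError(f"r2_percent must lie in [0, 100), got {r2_percent}")
    r2 = r2_percent / 100.0
    return (r2 / df1) / ((1.0 - r2) / df2)


def critical_f(alpha: float, df1: int, df2: int) -> float:
    """Upper-tail critical value of the F(df1, df2) distribution at level alpha."""
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    if df1 < 1 or df2 < 1:
        raise DomainError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    return float(stats.f.ppf(1.0 - alpha, df1, df2))


def assess_model(observed, predicted, df1: int, df2: int, alpha: float = 0.05) -> ModelQuality:
    """Full quality report for one model: R2, F, critical F and the verdict.

    A perfect fit (R2 = 100%) yields f_calc = +inf with ``f_capped`` set
    rather than an exception, so pipelines survive interpolating fits.
    """
    r2 = r_squared(observed, predicted)
    fc = critical_f(alpha, df1, df2)
    if r2 >= 100.0 - 1e-12:
        return ModelQuality(
            r2_percent=r2, f_calc=math.inf, df1=df1, df2=df2, f_crit=fc,
            significant=True, f_capped=True,
        )
    f_calc = f_from_r2(max(r2, 0.0), df1, df2)
    return ModelQuality(
        r2_percent=r2, f_calc=f_calc, df1=df1, df2=df2, f_crit=fc,
        significant=f_calc > fc,
    )
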