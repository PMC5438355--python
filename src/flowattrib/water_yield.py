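"""Water-yield-coefficient regressions and the pre/post slope comparison.

The water yield coefficient (WYC) is the OLS slope of growing-season
streamflow depth on growing-season precipitation: the marginal fraction of
precipitation leaving the catchment as river flow. A declining WYC between a
pre-restoration and post-restoration period signals a changed catchment
response beyond interannual climate variability.

Three estimators are provided: the simple slope, a partial slope controlling
for air temperature (coefficient on P from the two-regressor OLS of Q on P
and T, guarding against temperature-confounded trends), and an equality-of-
slopes test between two periods via the interaction term of a pooled
regression with a common error variance. Variables can be detrended first
(linear trend removed, mean preserved), computed within each period.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import statsmodels.api as sm

from .errors import SingularDesignError, ValidationError

_RANK_TOL = 1e-10


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    """A WYC estimate: slope (mm runoff per mm precipitation), its standard
    error and two-sided t-test p-value against zero."""

    slope: float
    intercept: float
    slope_se: float
    p_value: float
    n: int
    kind: str  # "simple" | "partial"
    detrended: bool

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValidationError("regression needs n >= 3")
        if self.slope_se < 0 or not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("invalid standard error or p-value")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class SlopeComparison:
    """Pre/post WYC difference with the interaction-term equality test."""

    slope_pre: float
    slope_post: float
    difference: float
    p_value: float
    test: str = "interaction t-test (pooled error variance)"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _check_full_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X, tol=_RANK_TOL * max(1.0, np.abs(X).max())) < X.shape[1]:
        raise SingularDesignError("design matrix is rank-deficient")


def linear_trend(years, values) -> tuple[float, float]:
    """OLS fit of value against calendar year; returns (slope per year,
    intercept at year 0). Raises for fewer than 2 distinct years."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.size < 2 or np.unique(years).size < 2:
        raise SingularDesignError("linear_trend needs >= 2 distinct years")
    slope, intercept = np.polyfit(years, values, 1)
    return float(slope), float(intercept)


def detrend(years, values) -> np.ndarray:
    """Remove the OLS linear trend, preserving the mean.

    The result has zero fitted trend and the same mean as the input;
    applying detrend twice equals applying it once (idempotent).
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.size < 3:
        raise SingularDesignError("detrend needs >= 3 years")
    slope, intercept = linear_trend(years, values)
    return values - (slope * years + intercept) + values.mean()


def water_yield_coefficient(
    P, Q, years=None, detrended: bool = False
) -> RegressionResult:
    """OLS slope of streamflow on precipitation (the WYC).

    With ``detrended=True`` both series are linearly detrended against
    ``years`` first (years then required). The slope equals
    cov(P, Q)/var(P); the p-value is the two-sided t-test on the slope.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.size != Q.size:
        raise ValidationError("P and Q must be aligned")
    if P.size < 3:
        raise ValidationError("WYC needs n >= 3")
    if detrended:
        if years is None:
            raise ValidationError("detrended WYC requires years")
        P = detrend(years, P)
        Q = detrend(years, Q)
    X = sm.add_constant(P, has_constant="add")
    _check_full_rank(X)
    fit = sm.OLS(Q, X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n=int(P.size),
        kind="simple",
        detrended=detrended,
    )


def partial_wyc(P, T, Q, years=None, detrended: bool = False) -> RegressionResult:
    """Partial WYC: the coefficient on P in the OLS of Q on (P, T).

    Controls for the indirect effect of temperature on streamflow; when T is
    orthogonal to P in sample it coincides with the simple slope
    (Frisch-Waugh). Raises :class:`SingularDesignError` for collinear
    regressors.
    """
    P = np.asarray(P, dtype=float)
    T = np.asarray(T, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if not (P.size == T.size == Q.size):
        raise ValidationError("P, T, Q must be aligned")
    if P.size < 4:
        raise ValidationError("partial WYC needs n >= 4")
    if detrended:
        if years is None:
            raise ValidationError("detrended partial WYC requires years")
        P, T, Q = detrend(years, P), detrend(years, T), detrend(years, Q)
    X = sm.add_constant(np.column_stack([P, T]), has_constant="add")
    _check_full_rank(X)
    fit = sm.OLS(Q, X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n=int(P.size),
        kind="partial",
        detrended=detrended,
    )


def compare_wyc(pre, post, detrended: bool = False) -> SlopeComparison:
    """Test equality of the WYC between two periods.

    ``pre`` and ``post`` are ``(years, P, Q)`` triples. Fits the pooled
    regression Q ~ P + era + P:era; the reported difference is the
    interaction coefficient (slope_post - slope_pre, exactly) and the
    p-value is its two-sided t-test under a pooled error variance.
    Detrending, when requested, is applied within each period.
    """
    parts = []
    for (years, P, Q), era in ((pre, 0.0), (post, 1.0)):
        P = np.asarray(P, dtype=float)
        Q = np.asarray(Q, dtype=float)
        years = np.asarray(years, dtype=float)
        if detrended:
            P = detrend(years, P)
            Q = detrend(years, Q)
        parts.append((P, Q, np.full(P.size, era)))
    P = np.concatenate([p[0] for p in parts])
    Q = np.concatenate([p[1] for p in parts])
    era = np.concatenate([p[2] for p in parts])
    X = sm.add_constant(np.column_stack([P, era, P * era]), has_constant="add")
    _check_full_rank(X)
    fit = sm.OLS(Q, X).fit()
    slope_pre = float(fit.params[1])
    diff = float(fit.params[3])
    return SlopeComparison(
        slope_pre=slope_pre,
        slope_post=slope_pre + diff,
        difference=diff,
        p_value=float(fit.pvalues[3]),
    )
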