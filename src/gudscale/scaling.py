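"""Scaling inference: power-law and logit-link fits, correlations, ANOVA.

Descriptors are related to body size or abundance as power laws
``Y = a * X**b`` fitted by ordinary least squares after log-log
transformation (natural logs; the base only shifts intercepts).
Descriptors that are fractions (resource exploitation) are instead fitted
on the logit scale against log size with a binomial likelihood, and fit
quality is reported as McFadden's pseudo-R-squared
``1 - lnL_fit / lnL_null``.  Pearson's product-moment correlation (with a
Fisher-z 95% CI) accompanies every fit, and a one-way fixed-effects ANOVA
tests treatment effects on residual disk charges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ScalingFit",
    "PearsonResult",
    "AnovaResult",
    "fit_power_law",
    "fit_logit_fraction",
    "pearson_with_ci",
    "residual_charge_anova",
]


@dataclass(frozen=True)
class ScalingFit:
    """A fitted scaling relationship.

    For the log-log link, ``intercept`` is the back-transformed coefficient
    ``a`` of ``Y = a X**b`` and ``slope`` the exponent ``b``; for the
    logit-log link the parameters are on the linear predictor scale
    ``logit(y) = intercept + slope * ln(x)``.  CIs are 95% half-widths.
    ``r_squared`` holds the OLS R-squared (log-log) or McFadden's
    pseudo-R-squared (logit-log).
    """

    link: str
    intercept: float
    slope: float
    intercept_ci95: float
    slope_ci95: float
    r_squared: float
    r_pearson: float
    r_ci95: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PearsonResult:
    r: float
    ci_low: float
    ci_high: float
    ci95_halfwidth: float
    p_value: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


def _validate_positive(name: str, values: np.ndarray) -> None:
    bad = np.flatnonzero(~(values > 0) | ~np.isfinite(values))
    if bad.size:
        raise ValueError(
            f"{name} must be strictly positive and finite for log transformation; "
            f"offending rows: {bad.tolist()}"
        )


def fit_power_law(x, y) -> ScalingFit:
    """Fit ``Y = a * X**b`` by OLS on natural-log transformed data.

    Returns the back-transformed intercept ``a``, the exponent ``b`` with
    t-based 95% CIs (the intercept CI half-width is the half-range of the
    back-transformed bounds), the log-log R-squared, and Pearson's r on the
    log-log pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError(f"need n >= 3 observations, got {x.size}")
    _validate_positive("x", x)
    _validate_positive("y", y)
    lx, ly = np.log(x), np.log(y)
    res = sm.OLS(ly, sm.add_constant(lx)).fit()
    ci = res.conf_int(alpha=0.05)
    a = math.exp(res.params[0])
    a_ci = (math.exp(ci[0, 1]) - math.exp(ci[0, 0])) / 2.0
    pear = pearson_with_ci(lx, ly)
    return ScalingFit(
        link="log-log",
        intercept=a,
        slope=float(res.params[1]),
        intercept_ci95=a_ci,
        slope_ci95=float((ci[1, 1] - ci[1, 0]) / 2.0),
        r_squared=float(res.rsquared),
        r_pearson=pear.r,
        r_ci95=pear.ci95_halfwidth,
        p_value=pear.p_value,
        n=int(x.size),
    )


def _bernoulli_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))


def fit_logit_fraction(x, y, eps: float = 1e-6) -> ScalingFit:
    """Fit a fraction against log x through a logit link.

    Model: ``y ~ logistic(intercept + slope * ln(x))``, estimated as a
    binomial-family GLM on the (0,1) fractions.  Boundary values are nudged
    into the open interval by ``eps``.  Fit quality is McFadden's
    pseudo-R-squared ``1 - lnL_fit / lnL_null`` with the Bernoulli-form
    likelihood evaluated at the fitted and the intercept-only (grand-mean)
    model.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError(f"need n >= 3 observations, got {x.size}")
    _validate_positive("x", x)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("fractions must lie in [0, 1]")
    y = np.clip(y, eps, 1.0 - eps)
    lx = sm.add_constant(np.log(x))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, lx, family=sm.families.Binomial()).fit()
    mu = np.asarray(res.mu, dtype=float)
    ll_fit = _bernoulli_loglik(y, mu)
    ll_null = _bernoulli_loglik(y, np.full_like(y, y.mean()))
    pseudo_r2 = 0.0 if ll_null == 0 else 1.0 - ll_fit / ll_null
    # numerical floor: the null model is nested in the fit, so ll_fit >= ll_null
    pseudo_r2 = max(pseudo_r2, 0.0)
    ci = res.conf_int(alpha=0.05)
    pear = pearson_with_ci(np.log(x), np.log(y / (1.0 - y)))
    return ScalingFit(
        link="logit-log",
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        intercept_ci95=float((ci[0, 1] - ci[0, 0]) / 2.0),
        slope_ci95=float((ci[1, 1] - ci[1, 0]) / 2.0),
        r_squared=float(pseudo_r2),
        r_pearson=pear.r,
        r_ci95=pear.ci95_halfwidth,
        p_value=pear.p_value,
        n=int(x.size),
    )


def pearson_with_ci(x, y) -> PearsonResult:
    """Pearson's r with a Fisher-z 95% CI and a two-sided t-test p-value.

    Zero variance in either variable makes r undefined; the result is
    returned with nan statistics and ``degenerate=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError(f"need n >= 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: Pearson correlation undefined", stacklevel=2)
        return PearsonResult(
            math.nan, math.nan, math.nan, math.nan, math.nan, int(x.size), True
        )
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=0.95)
    return PearsonResult(
        r=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        ci95_halfwidth=float((ci.high - ci.low) / 2.0),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def residual_charge_anova(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA across treatment groups of disk charges."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs >= 2 values")
    f, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    return AnovaResult(float(f), k - 1, n - k, float(p))
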