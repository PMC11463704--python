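"""Group-level statistics computed from their textbook formulas.

Welch's unequal-variance two-sample t-test, simple (one-predictor)
ordinary least squares with the R^2/F summary, the one-way ANOVA
between/within sum-of-squares decomposition, and a BIC-approximation
Bayes factor for nested linear models.  Inputs are either raw value
collections or printed summary moments (mean, SD, n), so reported group
comparisons can be recomputed directly from published tables.

The unit of analysis throughout is the subject-by-condition-level mean
percentage: regressions and ANOVAs pool one point per subject per level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SampleMoments",
    "WelchResult",
    "RegressionResult",
    "AnovaResult",
    "BayesFactorResult",
    "moments",
    "welch_t",
    "welch_t_from_values",
    "simple_regression",
    "one_way_anova",
    "bf_from_bics",
    "anova_bayes_factor",
    "regression_bayes_factor",
]


class SampleMoments(NamedTuple):
    """Summary moments of one sample: mean, sample SD (n-1), and n."""

    mean: float
    sd: float
    n: int


def moments(values: Sequence[float]) -> SampleMoments:
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 values, got {x.size}")
    return SampleMoments(float(x.mean()), float(x.std(ddof=1)), int(x.size))


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    f: float
    df_num: int
    df_den: int
    p: float


class AnovaResult(NamedTuple):
    f: float
    df_between: int
    df_within: int
    p: float
    ss_between: float
    ss_within: float
    ss_total: float


class BayesFactorResult(NamedTuple):
    bf10: float
    method: str


def welch_t(a: SampleMoments, b: SampleMoments) -> WelchResult:
    """Welch's two-sample t-test from summary moments.

    t = (mean_a - mean_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom and a two-sided p-value from
    the t distribution.
    """
    a, b = SampleMoments(*a), SampleMoments(*b)
    if a.n < 2 or b.n < 2:
        raise ValueError("each sample needs n >= 2")
    if a.sd < 0 or b.sd < 0:
        raise ValueError("standard deviations must be non-negative")
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if va + vb == 0:
        raise ValueError("both samples have zero variance; t is undefined")
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)))


def welch_t_from_values(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's t-test from raw per-subject values (delegates to moments)."""
    return welch_t(moments(a), moments(b))


def simple_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on a single predictor x.

    Returns the slope, intercept, coefficient of determination and the
    model F statistic on (1, N - 2) degrees of freedom with its
    two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("x is constant; slope is undefined")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))

    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    ss_model = slope * sxy
    ss_resid = max(syy - ss_model, 0.0)
    # constant y: no variance to explain, R^2 = 0 by convention
    r2 = 0.0 if syy == 0.0 else ss_model / syy
    df_den = n - 2
    if syy == 0.0:
        return RegressionResult(float(slope), intercept, 0.0, 0.0, 1,
                                int(df_den), 1.0)
    if ss_resid == 0.0:
        f = np.inf
        p = 0.0
    else:
        f = ss_model / (ss_resid / df_den)
        p = float(stats.f.sf(f, 1, df_den))
    return RegressionResult(float(slope), intercept, float(r2), float(f),
                            1, int(df_den), min(p, 1.0))


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way ANOVA from the between/within sum-of-squares decomposition."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    allx = np.concatenate(gs)
    grand = allx.mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in gs))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in gs))
    ss_total = float(np.sum((allx - grand) ** 2))
    df_b = len(gs) - 1
    df_w = allx.size - len(gs)
    if ss_within == 0.0:
        f = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, min(p, 1.0),
                       ss_between, ss_within, ss_total)


# -- Bayes factors (BIC approximation) -------------------------------------

_BIC_METHOD = "BIC approximation"


def bf_from_bics(bic_null: float, bic_alt: float) -> BayesFactorResult:
    """BF10 = exp((BIC_null - BIC_alt) / 2).

    Values below 1 favour the null; the unit-information-prior BIC
    approximation is coarse and is labelled as such in every result.
    """
    return BayesFactorResult(float(np.exp((bic_null - bic_alt) / 2.0)),
                             _BIC_METHOD)


def _gaussian_bic(ss_resid: float, n: int, n_params: int) -> float:
    if n <= 0 or ss_resid < 0:
        raise ValueError("invalid BIC inputs")
    ss = max(ss_resid, 1e-300)
    return n * np.log(ss / n) + n_params * np.log(n)


def anova_bayes_factor(groups: Sequence[Sequence[float]]) -> BayesFactorResult:
    """Evidence for a group-mean model over a grand-mean model.

    Fits both linear models by least squares and compares their BICs;
    BF10 < 1 is evidence for the absence of a group effect.
    """
    res = one_way_anova(groups)
    n = res.df_within + res.df_between + 1
    bic_null = _gaussian_bic(res.ss_total, n, 1)
    bic_alt = _gaussian_bic(res.ss_within, n, res.df_between + 1)
    return bf_from_bics(bic_null, bic_alt)


def regression_bayes_factor(x: Sequence[float],
                            y: Sequence[float]) -> BayesFactorResult:
    """Evidence for a linear trend in x over an intercept-only model."""
    reg = simple_regression(x, y)
    y = np.asarray(y, dtype=float)
    n = y.size
    syy = float(np.sum((y - y.mean()) ** 2))
    ss_resid = syy * (1.0 - reg.r_squared)
    bic_null = _gaussian_bic(syy, n, 1)
    bic_alt = _gaussian_bic(ss_resid, n, 2)
    return bf_from_bics(bic_null, bic_alt)
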