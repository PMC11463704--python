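"""Bayesian estimation of the population prevalence of a within-subject effect.

Given that ``k`` of ``n`` independently tested participants reached
per-subject significance, two posteriors over the population prevalence
``gamma`` (the fraction of the population in whom the effect is truly
present) are available, both under a uniform prior on [0, 1]:

``simple_beta``
    The significance count is treated as a direct binomial sample of
    prevalence: posterior Beta(1 + k, 1 + n - k).  This is the verbal
    "add one to each count" recipe.

``test_calibrated`` (default)
    The probability that a subject's test comes out significant is

        theta(gamma) = alpha_fp + (1 - alpha_fp) * gamma,

    where ``alpha_fp`` is the per-subject test's false-positive rate:
    subjects without the effect still reach significance at rate
    ``alpha_fp``.  The posterior on gamma is proportional to
    ``theta^k (1 - theta)^(n - k)``; its mode has the closed form
    ``max(0, (k/n - alpha_fp) / (1 - alpha_fp))``.  With ``alpha_fp = 0``
    the two models coincide.

Both posteriors are the same object mathematically: a Beta(k+1, n-k+1)
distribution on theta truncated to [alpha_fp, 1], mapped linearly to the
gamma scale; all density, CDF, mode and interval computations share that
representation.  Interval summaries use the highest-posterior-density
interval (HPDI): the shortest interval containing the requested posterior
mass, every density value inside of which exceeds every value outside.
The conventional mass here is 0.96.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BetaParams",
    "PrevalencePosterior",
    "PrevalenceEstimate",
    "posterior",
    "map_estimate",
    "hpdi",
    "estimate",
    "prevalence_curve",
    "curve_table",
]

MODELS = ("simple_beta", "test_calibrated")
DEFAULT_HPDI_MASS = 0.96


class BetaParams(NamedTuple):
    alpha: float
    beta: float


@dataclass(frozen=True)
class PrevalencePosterior:
    """Normalized posterior density over prevalence gamma on [0, 1]."""

    model: str
    k: int
    n: int
    alpha_fp: float = 0.0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.n <= 0:
            raise ValueError(f"n must be a positive number of subjects, got {self.n}")
        if not 0 <= self.k <= self.n:
            raise ValueError(f"need 0 <= k <= n, got k={self.k}, n={self.n}")
        if not 0.0 <= self.alpha_fp < 1.0:
            raise ValueError(f"alpha_fp must be in [0, 1), got {self.alpha_fp}")

    # -- internal truncated-beta representation on the theta scale --------

    @property
    def _a(self) -> float:
        """Lower truncation point of theta; 0 for the simple model."""
        return self.alpha_fp if self.model == "test_calibrated" else 0.0

    @property
    def beta_params(self) -> BetaParams:
        """Shape parameters of the (possibly truncated) beta on theta."""
        return BetaParams(self.k + 1.0, self.n - self.k + 1.0)

    @property
    def _dist(self):
        ab = self.beta_params
        return stats.beta(ab.alpha, ab.beta)

    @property
    def _norm(self) -> float:
        """P(theta >= a) under the untruncated beta."""
        return float(self._dist.sf(self._a))

    def _theta(self, gamma):
        return self._a + (1.0 - self._a) * np.asarray(gamma, dtype=float)

    # -- public density interface -----------------------------------------

    def pdf(self, gamma):
        """Posterior density at gamma (vectorized); 0 outside [0, 1]."""
        g = np.asarray(gamma, dtype=float)
        inside = (g >= 0.0) & (g <= 1.0)
        th = self._theta(np.clip(g, 0.0, 1.0))
        d = (1.0 - self._a) * self._dist.pdf(th) / self._norm
        out = np.where(inside, d, 0.0)
        return out if out.ndim else float(out)

    def logpdf(self, gamma):
        g = np.asarray(gamma, dtype=float)
        th = self._theta(np.clip(g, 0.0, 1.0))
        with np.errstate(divide="ignore"):
            lp = (np.log1p(-self._a) + self._dist.logpdf(th)
                  - np.log(self._norm))
            out = np.where((g >= 0.0) & (g <= 1.0), lp, -np.inf)
        return out if out.ndim else float(out)

    def cdf(self, gamma):
        g = np.clip(np.asarray(gamma, dtype=float), 0.0, 1.0)
        th = self._theta(g)
        out = (self._dist.cdf(th) - self._dist.cdf(self._a)) / self._norm
        return out if out.ndim else float(out)

    def ppf(self, q):
        """Quantile function on the gamma scale."""
        q = np.asarray(q, dtype=float)
        lo = self._dist.cdf(self._a)
        th = self._dist.ppf(lo + q * (1.0 - lo))
        out = (th - self._a) / (1.0 - self._a)
        out = np.clip(out, 0.0, 1.0)
        return out if out.ndim else float(out)

    def grid(self, num: int = 2001):
        """(gamma, density) arrays on a uniform grid over [0, 1]."""
        g = np.linspace(0.0, 1.0, num)
        return g, self.pdf(g)


def posterior(k: int, n: int, model: str = "test_calibrated",
              alpha_fp: float = 0.05) -> PrevalencePosterior:
    """Construct the prevalence posterior for a significance count.

    Parameters
    ----------
    k, n
        Number of individually significant participants and the number
        tested.
    model
        ``test_calibrated`` (default) or ``simple_beta``.
    alpha_fp
        Per-subject false-positive rate; only the test-calibrated model
        uses it.
    """
    if model == "simple_beta":
        alpha_fp = 0.0
    return PrevalencePosterior(model=model, k=int(k), n=int(n),
                               alpha_fp=float(alpha_fp))


def map_estimate(post: PrevalencePosterior) -> float:
    """Posterior mode of prevalence (closed form).

    On the theta scale the Beta(k+1, n-k+1) mode is k/n; mapping through
    the link and clamping to the truncated support gives
    ``clip((k/n - alpha_fp) / (1 - alpha_fp), 0, 1)``.  For the simple
    model this reduces to the usual beta-mode formula (alpha-1)/(alpha+beta-2),
    with the boundary conventions mode 0 at k = 0 and mode 1 at k = n.
    """
    a = post._a
    return float(np.clip((post.k / post.n - a) / (1.0 - a), 0.0, 1.0))


def hpdi(post: PrevalencePosterior, mass: float = DEFAULT_HPDI_MASS,
         tol: float = 1e-10) -> tuple[float, float]:
    """Highest-posterior-density interval on the gamma scale.

    The density is unimodal, so the HPDI is found by bisecting on a
    horizontal density threshold: for each candidate threshold the two
    endpoints where the density crosses it are located by root-finding on
    either side of the mode (clamped to a boundary where the density is
    monotone), and the threshold is adjusted until the enclosed posterior
    mass matches ``mass``.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0, 1), got {mass}")

    mode = map_estimate(post)
    f_mode = float(post.pdf(mode))
    f_lo_end = float(post.pdf(0.0))
    f_hi_end = float(post.pdf(1.0))

    def interval_at(height: float) -> tuple[float, float]:
        if f_lo_end >= height or mode <= 0.0:
            lo = 0.0
        else:
            lo = optimize.brentq(lambda g: float(post.pdf(g)) - height,
                                 0.0, mode, xtol=1e-13)
        if f_hi_end >= height or mode >= 1.0:
            hi = 1.0
        else:
            hi = optimize.brentq(lambda g: float(post.pdf(g)) - height,
                                 mode, 1.0, xtol=1e-13)
        return lo, hi

    def mass_at(height: float) -> float:
        lo, hi = interval_at(height)
        return float(post.cdf(hi) - post.cdf(lo))

    t_lo, t_hi = 0.0, f_mode
    for _ in range(100):
        t_mid = 0.5 * (t_lo + t_hi)
        if mass_at(t_mid) > mass:
            t_lo = t_mid
        else:
            t_hi = t_mid
        if t_hi - t_lo < tol * max(f_mode, 1.0):
            break
    lo, hi = interval_at(0.5 * (t_lo + t_hi))
    return float(lo), float(hi)


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Point and interval summary of a prevalence posterior."""

    map: float
    hpdi_low: float
    hpdi_high: float
    hpdi_mass: float
    posterior: PrevalencePosterior

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """(map, low, high) at reporting precision."""
        return (round(self.map, ndigits), round(self.hpdi_low, ndigits),
                round(self.hpdi_high, ndigits))


def estimate(k: int, n: int, model: str = "test_calibrated",
             alpha_fp: float = 0.05,
             mass: float = DEFAULT_HPDI_MASS) -> PrevalenceEstimate:
    """Posterior, MAP and HPDI for a significance count in one call."""
    post = posterior(k, n, model=model, alpha_fp=alpha_fp)
    lo, hi = hpdi(post, mass=mass)
    return PrevalenceEstimate(map=map_estimate(post), hpdi_low=lo,
                              hpdi_high=hi, hpdi_mass=mass, posterior=post)


def prevalence_curve(per_level_counts: dict, model: str = "test_calibrated",
                     alpha_fp: float = 0.05,
                     mass: float = DEFAULT_HPDI_MASS) -> dict:
    """Per-condition-level prevalence estimates plus the overall one.

    Parameters
    ----------
    per_level_counts
        Mapping from level key to ``(k_sig, n)``.  A key named
        ``"overall"`` is produced from the entry with that name if
        present; otherwise callers add it themselves.
    """
    return {key: estimate(k, n, model=model, alpha_fp=alpha_fp, mass=mass)
            for key, (k, n) in per_level_counts.items()}


def curve_table(estimates: dict, grid_points: int = 1001) -> tuple[pd.DataFrame,
                                                                   pd.DataFrame]:
    """Tabular export of prevalence estimates and their density curves.

    Returns (summary, curves): the summary has one row per level with the
    count, model, MAP and HPDI; the curves table is long-format
    (level, gamma, density) for plotting.
    """
    srows, crows = [], []
    for key, est in estimates.items():
        p = est.posterior
        srows.append({
            "level": key, "k_sig": p.k, "n": p.n, "model": p.model,
            "alpha_fp": p.alpha_fp, "map": est.map,
            "hpdi_low": est.hpdi_low, "hpdi_high": est.hpdi_high,
            "hpdi_mass": est.hpdi_mass,
        })
        g, d = p.grid(grid_points)
        crows.append(pd.DataFrame({"level": key, "gamma": g, "density": d}))
    return (pd.DataFrame(srows),
            pd.concat(crows, ignore_index=True) if crows else pd.DataFrame())
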