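"""Limiting-dilution estimation of initiating-cell frequency.

In a limiting dilution assay, wells seeded with d cells fail to form a
sphere with probability exp(−F·d) under the single-hit Poisson model,
where F is the frequency of sphere-initiating cells. The frequency is
estimated by least squares on the observed negative-well fractions, and
two groups are compared with the extra sum-of-squares F test: a shared-F
fit of both experiments against separate per-group fits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._errors import InsufficientDesignError, ParameterError, ValidationError

_F_LO, _F_HI = 1e-9, 10.0  # search bounds on the frequency (1/cells)


@dataclass
class LdaExperiment:
    """Well counts per seeding dose for one group."""

    doses: np.ndarray  # cells per well, strictly increasing
    n_wells: np.ndarray
    n_negative: np.ndarray  # wells without sphere growth
    group: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, float)
        self.n_wells = np.asarray(self.n_wells, int)
        self.n_negative = np.asarray(self.n_negative, int)
        if not (len(self.doses) == len(self.n_wells) == len(self.n_negative)):
            raise ParameterError("dose/well/negative vectors differ in length")
        if np.any(self.doses <= 0):
            raise ValidationError("doses must be > 0")
        if np.any(np.diff(self.doses) <= 0):
            raise ValidationError("doses must be strictly increasing")
        if np.any(self.n_negative < 0) or np.any(self.n_negative > self.n_wells):
            raise ValidationError("need 0 <= n_negative <= n_wells")
        if np.any(self.n_wells == 0):
            keep = self.n_wells > 0
            warnings.warn("dropping dose levels with 0 wells", stacklevel=2)
            self.doses = self.doses[keep]
            self.n_wells = self.n_wells[keep]
            self.n_negative = self.n_negative[keep]

    @property
    def frac_negative(self) -> np.ndarray:
        return self.n_negative / self.n_wells


@dataclass
class LdaFit:
    F: float  # initiating-cell frequency, 1/cells
    ci95: tuple[float, float]
    rss: float
    n_points: int
    flag: str = ""  # "", "lower_bound" (all positive), "upper_bound" (all negative)

    @property
    def one_in(self) -> float:
        """Frequency expressed as 1 cell in N."""
        return 1.0 / self.F


def _rss(F: float, exps: list[LdaExperiment]) -> float:
    return float(
        sum(np.sum((e.frac_negative - np.exp(-F * e.doses)) ** 2) for e in exps)
    )


def _minimize_F(exps: list[LdaExperiment]) -> tuple[float, float]:
    """Best-fitting shared frequency over one or more experiments."""
    grid = np.logspace(math.log10(_F_LO), math.log10(_F_HI), 200)
    coarse = grid[int(np.argmin([_rss(F, exps) for F in grid]))]
    res = optimize.minimize_scalar(
        lambda t: _rss(10.0**t, exps),
        bounds=(math.log10(coarse) - 1.0, math.log10(coarse) + 1.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    F_hat = 10.0**res.x
    return F_hat, _rss(F_hat, exps)


def fit_frequency(exp: LdaExperiment) -> LdaFit:
    """Least-squares single-hit fit of P(negative | d) = exp(−F·d).

    The 95% CI is profile-style: the set of F whose RSS stays within the
    F-distribution acceptance region around the minimum. Saturated
    designs (all wells positive, or all negative) return a bound with a
    flag instead of a point estimate.
    """
    if len(exp.doses) < 3:
        raise InsufficientDesignError("need >= 3 dose levels")
    frac = exp.frac_negative
    flag = ""
    if np.all(exp.n_negative == 0):
        flag = "lower_bound"  # F at least ~1/min dose; unidentifiable above
    elif np.all(exp.n_negative == exp.n_wells):
        flag = "upper_bound"  # no events: F at most ~1/(max dose · wells)
    F_hat, rss = _minimize_F([exp])
    df = max(len(exp.doses) - 1, 1)
    crit = rss * (1.0 + stats.f.ppf(0.95, 1, df) / df)

    def edge(lo: float, hi: float) -> float:
        g = lambda t: _rss(10.0**t, [exp]) - crit
        try:
            return 10.0 ** optimize.brentq(g, lo, hi)
        except ValueError:
            return 10.0**hi if hi > math.log10(F_hat) else 10.0**lo

    lt = math.log10(max(F_hat, _F_LO))
    ci = (edge(math.log10(_F_LO), lt), edge(lt, math.log10(_F_HI)))
    return LdaFit(F=F_hat, ci95=ci, rss=rss, n_points=len(exp.doses), flag=flag)


@dataclass
class LdaComparison:
    fit_a: LdaFit
    fit_b: LdaFit
    shared_F: float
    rss_shared: float
    rss_separate: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float


def compare_frequencies(a: LdaExperiment, b: LdaExperiment) -> LdaComparison:
    """Extra sum-of-squares F test of equal initiating-cell frequency.

    Fits a single shared F to both experiments versus separate
    frequencies; F = ((RSS_shared − RSS_sep)/1) / (RSS_sep/df_sep) with
    df_sep = (n_a + n_b) − 2, and p from the F(1, df_sep) distribution.
    """
    fit_a, fit_b = fit_frequency(a), fit_frequency(b)
    rss_sep = fit_a.rss + fit_b.rss
    shared_F, rss_shared = _minimize_F([a, b])
    df_sep = len(a.doses) + len(b.doses) - 2
    if df_sep <= 0:
        raise InsufficientDesignError("no residual degrees of freedom")
    # shared is nested in separate; numerical jitter can make the
    # difference minutely negative or minutely positive for identical data
    extra = max(rss_shared - rss_sep, 0.0)
    if extra <= 1e-9 * (rss_sep + 1e-12):
        extra = 0.0
    if rss_sep == 0.0:
        f_stat = 0.0 if extra == 0.0 else math.inf
    else:
        f_stat = extra / (rss_sep / df_sep)
    p = float(stats.f.sf(f_stat, 1, df_sep)) if math.isfinite(f_stat) else 0.0
    return LdaComparison(
        fit_a=fit_a, fit_b=fit_b, shared_F=shared_F,
        rss_shared=rss_shared, rss_separate=rss_sep,
        f_statistic=f_stat, df=(1, df_sep), p_value=p,
    )
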