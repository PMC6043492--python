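"""Incidence rates and overlap-corrected random-effects pooling.

These are the arithmetic pieces of a two-database pharmacoepidemiologic
validation: exact Poisson confidence intervals for incidence rates per 100
person-years, DerSimonian-Laird random-effects pooling of per-database log
hazard ratios with inverse-variance weights, and a pooled-variance
correction for the fraction of patients expected to appear in both claims
databases:

    var_corrected = sum_i w_i^2 var_i
                    + w_1 w_2 * (n_1 var_1 + n_2 var_2) / (n_1 + n_2) * p_overlap

with normalized weights w_i, study variances var_i, sample sizes n_i and
an assumed overlap fraction p_overlap (0.2 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CohortCount",
    "StudyEstimate",
    "IncidenceRate",
    "DLResult",
    "PooledEstimate",
    "incidence_rate",
    "dersimonian_laird",
    "overlap_corrected_variance",
    "pool_two_databases",
]

Z_95 = 1.96


@dataclass(frozen=True)
class CohortCount:
    """Event count and follow-up time for one study arm in one database."""

    label: str
    events: int
    person_years: float

    def __post_init__(self) -> None:
        if self.events < 0:
            raise ValueError("events must be non-negative")
        if self.person_years <= 0:
            raise ValueError("person_years must be positive")


@dataclass(frozen=True)
class StudyEstimate:
    """Per-database effect estimate: log hazard ratio, its variance, sample size."""

    database: str
    log_hr: float
    variance: float
    n: int

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class IncidenceRate:
    """Rate per ``per`` person-years with an exact Poisson 95% CI."""

    rate: float
    ci_low: float
    ci_high: float
    events: int
    person_years: float
    per: float

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """Display rounding, half-up (so 0.145 -> 0.15); internals stay full precision."""
        return tuple(_round_half_up(x, ndigits) for x in (self.rate, self.ci_low, self.ci_high))


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def incidence_rate(c: CohortCount, per: float = 100.0) -> IncidenceRate:
    """Incidence rate = events / person-years x ``per``, with exact Poisson bounds.

    The 95% CI applies the Garwood chi-square bounds to the event count and
    scales them like the rate; zero events give a lower bound of exactly 0.
    """
    k = c.events
    lower_count = 0.0 if k == 0 else stats.chi2.ppf(0.025, 2 * k) / 2.0
    upper_count = stats.chi2.ppf(0.975, 2 * k + 2) / 2.0
    scale = per / c.person_years
    return IncidenceRate(
        rate=k * scale,
        ci_low=lower_count * scale,
        ci_high=upper_count * scale,
        events=k,
        person_years=c.person_years,
        per=per,
    )


@dataclass(frozen=True)
class DLResult:
    pooled_log_hr: float
    tau2: float
    weights: tuple[float, ...]
    q: float


def dersimonian_laird(estimates: Sequence[StudyEstimate]) -> DLResult:
    """Moment-based random-effects pooling with inverse-variance weights.

    Cochran's Q is computed under fixed-effect weights 1/var_i;
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); the final
    weights are proportional to 1/(var_i + tau^2) and normalized to sum 1.
    A single study is returned unchanged with tau^2 = 0.
    """
    if not estimates:
        raise ValueError("need at least one study estimate")
    effects = np.array([e.log_hr for e in estimates])
    variances = np.array([e.variance for e in estimates])
    k = len(estimates)
    if k == 1:
        return DLResult(float(effects[0]), 0.0, (1.0,), 0.0)
    w_fixed = 1.0 / variances
    fixed_mean = float(np.sum(w_fixed * effects) / np.sum(w_fixed))
    q = float(np.sum(w_fixed * (effects - fixed_mean) ** 2))
    denom = np.sum(w_fixed) - np.sum(w_fixed**2) / np.sum(w_fixed)
    tau2 = max(0.0, (q - (k - 1)) / denom)
    w_re = 1.0 / (variances + tau2)
    w_norm = w_re / np.sum(w_re)
    pooled = float(np.sum(w_norm * effects))
    return DLResult(pooled, float(tau2), tuple(float(w) for w in w_norm), q)


def overlap_corrected_variance(
    estimates: Sequence[StudyEstimate],
    weights: Sequence[float],
    p_overlap: float = 0.2,
) -> float:
    """Pooled variance inflated for partially overlapping study populations.

    Two-database specific: with normalized weights (w1, w2), raw study
    variances and sample sizes, adds
    w1*w2*(n1*var1 + n2*var2)/(n1+n2)*p_overlap to the usual sum of
    squared-weight variances. At p_overlap = 0 it reduces exactly to
    sum w_i^2 var_i; it is non-decreasing in p_overlap.
    """
    if len(estimates) != 2 or len(weights) != 2:
        raise ValueError("overlap correction is defined for exactly two databases")
    if not 0.0 <= p_overlap <= 1.0:
        raise ValueError("p_overlap must be in [0, 1]")
    if not math.isclose(sum(weights), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("weights must be normalized to sum to 1")
    (e1, e2), (w1, w2) = estimates, weights
    base = w1**2 * e1.variance + w2**2 * e2.variance
    shared = (e1.n * e1.variance + e2.n * e2.variance) / (e1.n + e2.n)
    return base + w1 * w2 * shared * p_overlap


@dataclass(frozen=True)
class PooledEstimate:
    """Overlap-corrected pooled hazard ratio for a two-database comparison."""

    pooled_log_hr: float
    tau2: float
    corrected_variance: float
    p_overlap: float
    hr: float
    ci_low: float
    ci_high: float
    weights: tuple[float, ...]


def pool_two_databases(
    estimates: Sequence[StudyEstimate], p_overlap: float = 0.2
) -> PooledEstimate:
    """DerSimonian-Laird pooling of two databases with overlap-corrected CI.

    HR = exp(pooled log HR); 95% CI = exp(pooled +/- 1.96 sqrt(corrected
    variance)). The correction uses the normalized random-effects weights
    and the raw study variances.
    """
    if len(estimates) != 2:
        raise ValueError("pool_two_databases needs exactly two estimates")
    dl = dersimonian_laird(estimates)
    var_c = overlap_corrected_variance(estimates, dl.weights, p_overlap=p_overlap)
    half = Z_95 * math.sqrt(var_c)
    return PooledEstimate(
        pooled_log_hr=dl.pooled_log_hr,
        tau2=dl.tau2,
        corrected_variance=var_c,
        p_overlap=p_overlap,
        hr=math.exp(dl.pooled_log_hr),
        ci_low=math.exp(dl.pooled_log_hr - half),
        ci_high=math.exp(dl.pooled_log_hr + half),
        weights=dl.weights,
    )
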