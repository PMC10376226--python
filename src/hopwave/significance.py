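"""Binomial critical-classification-rate criterion.

A leave-one-out classification experiment over n units yields k correct
predictions.  Under the null hypothesis of no class difference, k follows
a binomial distribution with success probability p0 = 0.5.  The critical
classification rate is the smallest k/n whose test p-value falls below a
(Bonferroni-adjusted) significance level; observed rates strictly above
that threshold are judged significant.

Two test conventions are provided because they disagree slightly at small
n: the exact binomial tail and the normal approximation to the test of a
proportion, z = (k/n - p0) / sqrt(p0 (1 - p0) / n), without continuity
correction.  The convention used is recorded in every verdict.  For
n = 23 at alpha = 0.05 Bonferroni-adjusted over 3 comparisons, the normal
approximation gives a critical rate of 17/23 = 73.9 %.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "CriticalRateSpec",
    "Verdict",
    "binomial_pvalue",
    "bonferroni",
    "critical_rate",
    "judge",
    "min_detectable_proportion",
]


@dataclass(frozen=True)
class CriticalRateSpec:
    """Parameters of the critical-rate computation."""

    n: int
    p0: float = 0.5
    alpha: float = 0.05
    m_comparisons: int = 3
    method: str = "normal-approximation"  # or "exact"
    sidedness: str = "one"  # or "two"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not 0 < self.p0 < 1:
            raise ConfigurationError("p0 must lie in (0, 1)")
        if self.m_comparisons < 1:
            raise ConfigurationError("m_comparisons must be >= 1")
        if self.method not in ("exact", "normal-approximation"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.sidedness not in ("one", "two"):
            raise ConfigurationError(f"unknown sidedness {self.sidedness!r}")


@dataclass(frozen=True)
class Verdict:
    significant: bool
    rate_percent: float
    threshold_percent: float
    method: str
    alpha_adjusted: float


def binomial_pvalue(k: int, n: int, p0: float = 0.5, sidedness: str = "one") -> float:
    """Exact binomial tail probability for k successes out of n.

    One-sided: P(X >= k).  Two-sided: twice the smaller tail, capped at 1.
    """
    if not 0 <= k <= n:
        raise ConfigurationError("k must satisfy 0 <= k <= n")
    upper = float(stats.binom.sf(k - 1, n, p0))
    if sidedness == "one":
        return upper
    lower = float(stats.binom.cdf(k, n, p0))
    return min(1.0, 2.0 * min(upper, lower))


def _normal_pvalue(k: int, n: int, p0: float, sidedness: str) -> float:
    se = (p0 * (1.0 - p0) / n) ** 0.5
    z = (k / n - p0) / se
    p = float(stats.norm.sf(z))
    if sidedness == "two":
        p = min(1.0, 2.0 * min(p, 1.0 - p))
    return p


def pvalue(k: int, n: int, spec: CriticalRateSpec) -> float:
    """p-value of k/n under the spec's method and sidedness."""
    if spec.method == "exact":
        return binomial_pvalue(k, n, spec.p0, spec.sidedness)
    return _normal_pvalue(k, n, spec.p0, spec.sidedness)


def bonferroni(alpha: float, m_comparisons: int) -> float:
    """Adjusted per-comparison significance level alpha / m."""
    if m_comparisons < 1:
        raise ConfigurationError("m_comparisons must be >= 1")
    return alpha / m_comparisons


def critical_rate(spec: CriticalRateSpec) -> dict:
    """Smallest k (and its rate) significant at the adjusted level.

    Returns a dict with ``k_critical``, ``rate_percent`` (one decimal),
    ``p_value`` at the critical k, the adjusted alpha, and the method.
    """
    alpha_adj = bonferroni(spec.alpha, spec.m_comparisons)
    for k in range(spec.n + 1):
        p = pvalue(k, spec.n, spec)
        if p < alpha_adj:
            return {
                "k_critical": k,
                "rate_percent": round(100.0 * k / spec.n, 1),
                "p_value": p,
                "alpha_adjusted": alpha_adj,
                "method": spec.method,
                "sidedness": spec.sidedness,
                "n": spec.n,
            }
    p_min = pvalue(spec.n, spec.n, spec)
    raise ConfigurationError(
        f"no k <= n={spec.n} reaches significance; minimum achievable p is {p_min:.4g}"
    )


def judge(rate_percent: float, spec: CriticalRateSpec) -> Verdict:
    """Judge an observed classification rate against the critical rate.

    Significance requires the observed rate to be strictly greater than
    the critical rate (rates exactly at threshold are not significant).
    """
    crit = critical_rate(spec)
    return Verdict(
        significant=bool(rate_percent > crit["rate_percent"]),
        rate_percent=float(rate_percent),
        threshold_percent=crit["rate_percent"],
        method=spec.method,
        alpha_adjusted=crit["alpha_adjusted"],
    )


def min_detectable_proportion(spec: CriticalRateSpec, power: float = 0.80) -> float:
    """Smallest true success probability detected with the given power.

    Reported alongside critical rates as a power diagnostic; never used
    as the significance threshold itself.
    """
    if not 0 < power < 1:
        raise ConfigurationError("power must lie in (0, 1)")
    k_crit = critical_rate(spec)["k_critical"]
    lo, hi = spec.p0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        achieved = float(stats.binom.sf(k_crit - 1, spec.n, mid))
        if achieved >= power:
            hi = mid
        else:
            lo = mid
    return hi
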