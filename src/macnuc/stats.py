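"""Two-sample statistics implemented from first principles.

The battery used throughout the analysis: Welch's t-test (raw-data and
summary-statistic pathways, one- and two-tailed), the two-sample
Kolmogorov–Smirnov test, the Mann–Whitney U test (exact by enumeration at
desk scale, normal approximation with tie correction otherwise), and
t-based 95% confidence intervals. Test statistics, Welch–Satterthwaite
degrees of freedom, rank handling and exact null distributions are
computed here; only the reference distributions (Student t, standard
normal, Kolmogorov) come from scipy.

Tail convention: ``alternative`` is one of "two-sided", "greater" or
"less"; one-tailed tests always take an explicit direction, "greater"
meaning the first sample's location exceeds the second's.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import kstwobign, norm
from scipy.stats import t as t_dist

logger = logging.getLogger(__name__)

__all__ = [
    "StatResult",
    "welch_t_summary",
    "welch_t",
    "ks_2sample",
    "mann_whitney_u",
    "mean_ci95",
]

_ALTERNATIVES = ("two-sided", "greater", "less")


@dataclass
class StatResult:
    """One test invocation: statistic, df (when defined), p-value, tails."""

    statistic: float
    df: Optional[float]
    p_value: float
    tails: str  # "one" | "two"
    test_name: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")


def _tail_p(stat: float, alternative: str, sf, cdf) -> float:
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(sf(stat), cdf(stat)))
    if alternative == "greater":
        return sf(stat)
    return cdf(stat)


def welch_t_summary(
    n1: int,
    mean1: float,
    sd1: float,
    n2: int,
    mean2: float,
    sd2: float,
    alternative: str = "two-sided",
) -> StatResult:
    """Welch's t-test from group summary statistics.

    t = (mean1 - mean2) / sqrt(sd1²/n1 + sd2²/n2), with degrees of
    freedom by the Welch–Satterthwaite approximation; p from Student-t
    tail(s). ``sd`` are sample standard deviations (ddof=1).
    """
    _check_alternative(alternative)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be > 0")
    v1 = sd1**2 / n1
    v2 = sd2**2 / n2
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = _tail_p(t, alternative,
                sf=lambda x: float(t_dist.sf(x, df)),
                cdf=lambda x: float(t_dist.cdf(x, df)))
    tails = "two" if alternative == "two-sided" else "one"
    return StatResult(statistic=float(t), df=float(df), p_value=float(p),
                      tails=tails, test_name="welch_t")


def welch_t(
    sample1: Sequence[float],
    sample2: Sequence[float],
    alternative: str = "two-sided",
) -> StatResult:
    """Welch's t-test on raw samples.

    Identical to :func:`welch_t_summary` applied to the samples' own
    n, mean and sd. Two zero-variance samples with equal means yield
    p = 1 by convention (with a warning) rather than 0/0.
    """
    _check_alternative(alternative)
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    sd1 = float(np.std(x, ddof=1))
    sd2 = float(np.std(y, ddof=1))
    if sd1 == 0.0 and sd2 == 0.0:
        if np.isclose(x.mean(), y.mean()):
            logger.warning("both samples constant and equal; p = 1 by convention")
            tails = "two" if alternative == "two-sided" else "one"
            return StatResult(statistic=0.0, df=float(x.size + y.size - 2),
                              p_value=1.0, tails=tails, test_name="welch_t")
        raise ValueError("both samples have zero variance but unequal means")
    return welch_t_summary(x.size, float(x.mean()), sd1,
                           y.size, float(y.mean()), sd2,
                           alternative=alternative)


def ks_2sample(sample1: Sequence[float], sample2: Sequence[float]) -> StatResult:
    """Two-sample Kolmogorov–Smirnov test (two-sided).

    D = sup |ECDF1 − ECDF2|, evaluated over the pooled sample. The
    p-value uses the asymptotic Kolmogorov distribution at the effective
    sample size n_e = n1·n2/(n1+n2), with the standard small-sample
    argument correction (sqrt(n_e) + 0.12 + 0.11/sqrt(n_e))·D.
    """
    x = np.sort(np.asarray(sample1, dtype=float))
    y = np.sort(np.asarray(sample2, dtype=float))
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    pooled = np.concatenate([x, y])
    cdf1 = np.searchsorted(x, pooled, side="right") / n1
    cdf2 = np.searchsorted(y, pooled, side="right") / n2
    d = float(np.max(np.abs(cdf1 - cdf2)))
    ne = n1 * n2 / (n1 + n2)
    lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * d
    p = float(np.clip(kstwobign.sf(lam), 0.0, 1.0))
    return StatResult(statistic=d, df=None, p_value=p, tails="two",
                      test_name="ks_2sample")


def _midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with tied values assigned their midrank."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of each U value under the null (no ties), U = 0..n1*n2.

    Classic recursion on the largest pooled element: if it comes from
    sample 1 it beats all j remaining sample-2 values, else it
    contributes nothing — f(i, j, u) = f(i-1, j, u-j) + f(i, j-1, u).
    """
    umax = n1 * n2
    # f[j, u] for the current i; i = 0: U must be 0 for any j
    f = np.zeros((n2 + 1, umax + 1), dtype=float)
    f[:, 0] = 1.0
    for _ in range(1, n1 + 1):
        new = np.zeros_like(f)
        new[0, 0] = 1.0  # no sample-2 elements left: U = 0
        for j in range(1, n2 + 1):
            new[j, j:] = f[j, : umax + 1 - j]  # largest element from sample 1
            new[j, :] += new[j - 1, :]  # largest element from sample 2
        f = new
    return f[n2]


def mann_whitney_u(
    sample1: Sequence[float],
    sample2: Sequence[float],
    alternative: str = "two-sided",
    exact_limit: int = 400,
) -> StatResult:
    """Mann–Whitney U test via rank sums with midrank ties.

    The reported statistic is U1, the number of (x, y) pairs with x > y
    (ties counted half): U1 = 0 when every value of ``sample1`` lies
    below ``sample2``, and n1·n2 in the opposite ordering. When there are
    no ties and n1·n2 <= ``exact_limit``, the p-value is exact from the
    full null distribution of U; otherwise a normal approximation with
    tie correction and continuity correction is used.
    """
    _check_alternative(alternative)
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if not has_ties and n1 * n2 <= exact_limit:
        counts = _u_null_counts(n1, n2)
        total = counts.sum()
        u_int = int(round(u1))
        p_greater = counts[u_int:].sum() / total
        p_less = counts[: u_int + 1].sum() / total
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(p_greater, p_less))
        elif alternative == "greater":
            p = p_greater
        else:
            p = p_less
        return StatResult(statistic=float(u1), df=None, p_value=float(p),
                          tails="two" if alternative == "two-sided" else "one",
                          test_name="mann_whitney_u_exact")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    sigma = math.sqrt(sigma2)
    if sigma == 0:
        p = 1.0
        z = 0.0
    else:
        if alternative == "greater":
            z = (u1 - mu - 0.5) / sigma
            p = float(norm.sf(z))
        elif alternative == "less":
            z = (u1 - mu + 0.5) / sigma
            p = float(norm.cdf(z))
        else:
            z = (u1 - mu - math.copysign(0.5, u1 - mu)) / sigma if u1 != mu else 0.0
            p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return StatResult(statistic=float(u1), df=None, p_value=p,
                      tails="two" if alternative == "two-sided" else "one",
                      test_name="mann_whitney_u_normal")


def mean_ci95(sample: Sequence[float]) -> tuple[float, float]:
    """Sample mean and t-based 95% CI halfwidth, t₀.₉₇₅,ₙ₋₁·sd/√n."""
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2 for a confidence interval")
    sd = float(np.std(x, ddof=1))
    half = float(t_dist.ppf(0.975, x.size - 1)) * sd / math.sqrt(x.size)
    return float(x.mean()), half
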