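"""Statistical primitives used across the screen audit.

The Jonckheere-Terpstra trend test and the conditional-MLE odds ratio for
Fisher's exact test are implemented here because no installed library exposes
them in the form the pipeline needs (tie-corrected normal approximation with
an exact small-sample mode; odds ratio by root-finding on the noncentral
hypergeometric mean). Pearson correlation and LOWESS are thin wrappers over
scipy/statsmodels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "JonckheereResult",
    "FisherResult",
    "jonckheere",
    "fisher_exact_2x2",
    "pearson_with_p",
    "lowess_fit",
    "benjamini_hochberg",
]


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra trend test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JonckheereResult:
    """Result of the Jonckheere-Terpstra test for an ordered trend.

    J is the sum over ordered group pairs (i < j) of the number of
    observation pairs (x in group i, y in group j) with x < y, counting
    ties as 1/2. Large J supports an increasing trend across groups.
    """

    statistic: float
    null_mean: float
    null_var: float
    z: float
    p_value: float
    alternative: str
    method: str
    n_groups: int


def _j_statistic(groups: Sequence[np.ndarray]) -> float:
    j = 0.0
    for a, b in itertools.combinations(groups, 2):
        diff = b[None, :] - a[:, None]
        j += float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
    return j


def _jonckheere_moments(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    # Tie-corrected null mean/variance (Hollander & Wolfe).
    ns = np.array([len(g) for g in groups], dtype=float)
    pooled = np.concatenate(groups)
    n = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)

    mean = (n * n - np.sum(ns**2)) / 4.0

    def f1(x):
        return np.sum(x * (x - 1) * (2 * x + 5))

    def f2(x):
        return np.sum(x * (x - 1) * (x - 2))

    def f3(x):
        return np.sum(x * (x - 1))

    var = (f1(np.array([n])) - f1(ns) - f1(t)) / 72.0
    if n > 2:
        var += f2(ns) * f2(t) / (36.0 * n * (n - 1) * (n - 2))
    var += f3(ns) * f3(t) / (8.0 * n * (n - 1))
    return mean, var


def _jonckheere_exact_p(groups: Sequence[np.ndarray], j_obs: float) -> float:
    """One-sided exact p (increasing) by full enumeration of assignments."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n = pooled.size
    idx = list(range(n))
    count = 0
    total = 0
    # Enumerate distinct assignments of pooled observations to ordered groups.
    def rec(remaining: list[int], gi: int, chosen: list[np.ndarray]):
        nonlocal count, total
        if gi == len(sizes) - 1:
            arrangement = chosen + [pooled[remaining]]
            total += 1
            if _j_statistic(arrangement) >= j_obs - 1e-12:
                count += 1
            return
        for comb in itertools.combinations(remaining, sizes[gi]):
            rest = [i for i in remaining if i not in set(comb)]
            rec(rest, gi + 1, chosen + [pooled[list(comb)]])

    rec(idx, 0, [])
    return count / total


def jonckheere(
    groups: Sequence[Sequence[float]],
    alternative: Literal["increasing", "decreasing"] = "increasing",
    method: Literal["auto", "normal", "exact"] = "auto",
    exact_n_max: int = 12,
) -> JonckheereResult:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    Parameters
    ----------
    groups
        Ordered sequence of numeric samples (the hypothesized ordering).
    alternative
        Direction of the trend under the alternative hypothesis.
    method
        "normal" uses the tie-corrected normal approximation; "exact"
        enumerates all assignments of the pooled observations to groups
        (feasible for small totals); "auto" selects exact when the pooled
        size is at most ``exact_n_max``.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in gs):
        raise ValueError("jonckheere: every group must be non-empty")
    if len(gs) < 2:
        raise ValueError("jonckheere: need at least 2 groups")
    import warnings

    if len(gs) == 2:
        warnings.warn("jonckheere: only 2 groups; equivalent to Mann-Whitney U")
    if alternative == "decreasing":
        gs_dir = gs[::-1]
    else:
        gs_dir = gs
    j = _j_statistic(gs_dir)
    mean, var = _jonckheere_moments(gs_dir)
    n_total = sum(g.size for g in gs)

    if method == "auto":
        method = "exact" if n_total <= exact_n_max else "normal"

    if var <= 0:
        z = 0.0
        p = 0.5
        meth = "normal"
    elif method == "exact":
        z = (j - mean) / math.sqrt(var)
        p = _jonckheere_exact_p(gs_dir, j)
        meth = "exact"
    else:
        z = (j - mean) / math.sqrt(var)
        p = float(stats.norm.sf(z))
        meth = "normal"
    return JonckheereResult(
        statistic=j,
        null_mean=mean,
        null_var=var,
        z=z,
        p_value=p,
        alternative=alternative,
        method=meth,
        n_groups=len(gs),
    )


# ---------------------------------------------------------------------------
# Fisher's exact test with conditional-MLE odds ratio
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    p_two_sided: float
    or_cmle: float
    or_sample: float
    degenerate: bool = False


def _cmle_odds_ratio(x: int, r1: int, r2: int, c1: int) -> float:
    """Conditional MLE of the odds ratio given all margins.

    Solves E_psi[X] = x where X follows Fisher's noncentral hypergeometric
    distribution on the support of the (0,0) cell.
    """
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    if x == lo:
        return 0.0
    if x == hi:
        return float("inf")
    support = np.arange(lo, hi + 1)
    log_binom = special.gammaln(r1 + 1) - special.gammaln(support + 1) \
        - special.gammaln(r1 - support + 1) \
        + special.gammaln(r2 + 1) - special.gammaln(c1 - support + 1) \
        - special.gammaln(r2 - c1 + support + 1)

    def mean_minus_x(log_psi: float) -> float:
        logw = log_binom + support * log_psi
        logw -= logw.max()
        w = np.exp(logw)
        return float(np.sum(support * w) / np.sum(w)) - x

    lo_b, hi_b = -1.0, 1.0
    while mean_minus_x(lo_b) > 0:
        lo_b *= 2
    while mean_minus_x(hi_b) < 0:
        hi_b *= 2
    log_psi = optimize.brentq(mean_minus_x, lo_b, hi_b, xtol=1e-12)
    return math.exp(log_psi)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> FisherResult:
    """Fisher's exact test on a 2x2 table.

    The two-sided p value sums hypergeometric point probabilities no larger
    than that of the observed table (the convention of R's ``fisher.test``).
    The odds ratio is the conditional maximum-likelihood estimate under
    Fisher's noncentral hypergeometric distribution.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("fisher_exact_2x2: need a 2x2 table of non-negative integers")
    t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    tab = ((a, b), (c, d))
    if min(r1, r2, c1, c2) == 0:
        return FisherResult(tab, 1.0, float("nan"), float("nan"), degenerate=True)
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    p = min(p, 1.0)
    or_sample = (a * d) / (b * c) if b * c > 0 else float("inf")
    or_cmle = _cmle_odds_ratio(a, r1, r2, c1)
    return FisherResult(tab, p, or_cmle, or_sample)


# ---------------------------------------------------------------------------
# Pearson correlation, LOWESS, multiple testing
# ---------------------------------------------------------------------------

def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p value.

    The p value is from the exact t transform t = r * sqrt((n-2)/(1-r^2)).
    Incomplete pairs (NaN in either vector) are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("pearson_with_p: length mismatch")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("pearson_with_p: need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_with_p: constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def lowess_fit(x: Sequence[float], y: Sequence[float], frac: float = 2.0 / 3.0) -> np.ndarray:
    """LOWESS fitted values at the input x, in input order."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0 < frac <= 1:
        raise ValueError("lowess_fit: frac must be in (0, 1]")
    if x.size < 5:
        raise ValueError("lowess_fit: need at least 5 points")
    out = _sm_lowess(y, x, frac=frac, return_sorted=False)
    return np.asarray(out, dtype=float)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.clip(ranked, 0, 1)
    return q
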