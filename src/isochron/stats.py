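"""Descriptive and comparison statistics.

Every quantification is summarized as mean ± SEM (sample sd, n−1
denominator).  Group comparisons use the two-tailed Mann-Whitney U test:
the exact permutation null is enumerated when the pooled sample is small
and tie-free, otherwise the tie-corrected normal approximation with
continuity correction is used.  The two-tailed p doubles the smaller
one-sided tail, capped at 1 — the convention of the common Wilcoxon
rank-sum implementations.

The U statistic, its exact null distribution, Pearson's r and the
log-normal ML fit are computed here from first principles; only the
normal- and t-distribution CDFs come from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "mean_sem",
    "mann_whitney_u",
    "ComparisonResult",
    "pearson",
    "fit_lognormal",
    "LogNormalFit",
    "change_metrics",
    "significance_stars",
]

#: Largest pooled sample for which the exact permutation null is enumerated.
EXACT_MAX_POOLED = 16


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean (sd with n−1 denominator).

    For n = 1 the SEM is reported as 0 (there is no spread estimate).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mean_sem requires at least one value")
    if v.size == 1:
        return float(v[0]), 0.0
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))


@dataclass
class ComparisonResult:
    group_labels: tuple[str, str]
    n1: int
    n2: int
    statistic_U: float
    p_two_tailed: float
    mean_sem_1: tuple[float, float]
    mean_sem_2: tuple[float, float]
    method: str  # exact_enumeration | normal_approx_tie_corrected
    degenerate: bool = False  # all pooled values identical

    def to_dict(self) -> dict:
        return {
            "group_labels": list(self.group_labels),
            "n1": self.n1, "n2": self.n2,
            "U": self.statistic_U, "p_two_tailed": self.p_two_tailed,
            "mean_1": self.mean_sem_1[0], "sem_1": self.mean_sem_1[1],
            "mean_2": self.mean_sem_2[0], "sem_2": self.mean_sem_2[1],
            "method": self.method, "degenerate": self.degenerate,
        }


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_v = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0  # average of ranks i+1..j+1
        i = j + 1
    return ranks


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    r1 = ranks[: len(a)].sum()
    return float(r1 - len(a) * (len(a) + 1) / 2.0)


def _exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-tailed p by full enumeration of the C(n1+n2, n1) labelings."""
    n1, n2 = len(a), len(b)
    pooled = np.sort(np.concatenate([a, b]))
    ranks = np.arange(1, n1 + n2 + 1)  # no ties by precondition
    total = math.comb(n1 + n2, n1)
    lo = hi = 0
    offset = n1 * (n1 + 1) / 2.0
    for combo in combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - offset
        if u <= u_obs + 1e-9:
            lo += 1
        if u >= u_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def mann_whitney_u(a, b, mode: str = "auto", labels: tuple[str, str] = ("a", "b")) -> ComparisonResult:
    """Two-tailed Mann-Whitney U (Wilcoxon rank-sum) test.

    ``mode='auto'`` enumerates the exact permutation null when
    ``n1 + n2 <= EXACT_MAX_POOLED`` and there are no ties, and otherwise
    uses the normal approximation with tie and continuity corrections.
    ``mode='exact'`` forces enumeration (error on ties), ``mode='approx'``
    forces the normal approximation.  A pooled sample of identical values
    is degenerate and reports p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups need at least one value")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    u = _u_statistic(a, b)

    if np.all(pooled == pooled[0]):
        return ComparisonResult(labels, n1, n2, u, 1.0, mean_sem(a), mean_sem(b),
                                "normal_approx_tie_corrected", degenerate=True)

    use_exact = (mode == "exact") or (
        mode == "auto" and not has_ties and n1 + n2 <= EXACT_MAX_POOLED
    )
    if use_exact:
        if has_ties:
            raise ValueError("exact enumeration requires tie-free data")
        p = _exact_p(a, b, u)
        method = "exact_enumeration"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            diff = u - mu
            cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
            z = (diff - cc) / math.sqrt(var) if diff != 0 else 0.0
            p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
        method = "normal_approx_tie_corrected"
    return ComparisonResult(labels, n1, n2, u, p, mean_sem(a), mean_sem(b), method)


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p from the t reference distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("pearson requires n >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = math.sqrt(float(xd.dot(xd)))
    sy = math.sqrt(float(yd.dot(yd)))
    if sx == 0 or sy == 0:
        raise ValueError("pearson requires nonzero variance in both variables")
    r = float(xd.dot(yd) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return r, min(1.0, p)


@dataclass
class LogNormalFit:
    logmean: float
    logsd: float
    n: int
    gof_pvalue: float | None  # normality of the logs (None when n < 8)


def fit_lognormal(values) -> LogNormalFit:
    """ML log-normal fit: moments of the log values, plus a normality GOF.

    The goodness-of-fit p-value is a D'Agostino-Pearson normality test on
    the logs (requires n ≥ 8; reported as None below that).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("fit_lognormal requires n >= 2")
    if np.any(v <= 0):
        raise ValueError("fit_lognormal requires strictly positive values")
    logs = np.log(v)
    logmean = float(logs.mean())
    logsd = float(logs.std(ddof=0))  # ML estimate
    gof = None
    if v.size >= 8 and logsd > 0:
        gof = float(sps.normaltest(logs).pvalue)
    return LogNormalFit(logmean=logmean, logsd=logsd, n=int(v.size), gof_pvalue=gof)


def change_metrics(before: float, after: float) -> dict[str, float]:
    """Percent change and fold change from ``before`` to ``after``."""
    if not before > 0:
        raise ValueError(f"before must be > 0, got {before}")
    return {
        "percent_change": 100.0 * (after - before) / before,
        "fold_change": after / before,
    }


def significance_stars(p: float) -> str:
    """Figure-legend style annotation: ns, *, **, ***."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
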