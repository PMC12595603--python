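"""Statistical primitives shared by every downstream stage.

Kept deliberately self-contained so the pipeline's inferential behaviour is
fully specified here: Pearson correlation with the t-transform p-value, the
two-sample Wilcoxon rank-sum test (exact null for small untied samples, a
tie- and continuity-corrected normal approximation otherwise), step-up
Benjamini–Hochberg adjustment, and the conditional (Fisher) exact test for
2x2 count tables. Only distribution functions come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import hypergeom as _hypergeom
from scipy.stats import norm as _norm
from scipy.stats import t as _t

__all__ = [
    "CorrelationResult",
    "RankTestResult",
    "StatsError",
    "pearson",
    "wilcoxon_rank_sum",
    "benjamini_hochberg",
    "fisher_exact",
    "significance_stars",
]

Sign = Literal["positive", "negative", "zero"]

# exact rank-sum null is enumerated up to this pooled size (no ties)
EXACT_RANKSUM_MAX_N = 16


class StatsError(ValueError):
    """Invalid input to a statistical primitive."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int

    @property
    def sign(self) -> Sign:
        if self.r > 0:
            return "positive"
        if self.r < 0:
            return "negative"
        return "zero"


@dataclass(frozen=True)
class RankTestResult:
    statistic: float  # rank sum W of the first sample
    p_value: float
    n1: int
    n2: int


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with two-sided p from t = r*sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise StatsError(f"need n >= 3 paired observations, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0 or sy == 0:
        raise StatsError("undefined correlation: a series has zero variance")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * _t.sf(abs(tstat), n - 2))
    return CorrelationResult(r=r, p_value=min(p, 1.0), n=n)


def _ranks_with_ties(pooled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks of ``pooled`` plus the tie-group sizes."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size, dtype=float)
    sorted_vals = pooled[order]
    ties = []
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        ties.append(j - i + 1)
        i = j + 1
    return ranks, np.asarray(ties)


def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """counts[u] = number of n1-subsets of ranks 1..n1+n2 with U statistic u."""
    # classic restricted-partition recurrence
    max_u = n1 * n2
    counts = np.zeros((n1 + 1, max_u + 1), dtype=float)
    counts[0, 0] = 1.0
    for item in range(1, n1 + n2 + 1):
        for k in range(min(item, n1), 0, -1):
            # adding rank `item` as the k-th chosen element contributes
            # item - k to U
            shift = item - k
            if shift > 0:
                counts[k, shift:] += counts[k - 1, : max_u + 1 - shift]
            else:
                counts[k] += counts[k - 1]
    return counts[n1]


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> RankTestResult:
    """Two-sided two-sample Wilcoxon rank-sum (Mann–Whitney) test.

    The exact permutation null of the U statistic is used when
    n1 + n2 <= 16 and the pooled data carry no ties; otherwise the normal
    approximation with tie correction and a 0.5 continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise StatsError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks, ties = _ranks_with_ties(pooled)
    w = float(ranks[:n1].sum())
    u1 = w - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1

    has_ties = np.any(ties > 1)
    if (n1 + n2) <= EXACT_RANKSUM_MAX_N and not has_ties:
        counts = _exact_u_counts(n1, n2)
        total = counts.sum()
        u_lo = int(round(min(u1, u2)))
        p = 2.0 * counts[: u_lo + 1].sum() / total
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        tie_term = float((ties**3 - ties).sum())
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var == 0:
            return RankTestResult(statistic=w, p_value=1.0, n1=n1, n2=n2)
        z = (max(u1, u2) - mu - 0.5) / np.sqrt(var)
        p = 2.0 * float(_norm.sf(z))
    return RankTestResult(statistic=w, p_value=min(1.0, p), n1=n1, n2=n2)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjustment; output in input order, monotone, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise StatsError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m, dtype=float)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def fisher_exact(table: Sequence[Sequence[float]]) -> float:
    """Two-sided conditional exact test for a 2x2 count table.

    Sums hypergeometric probabilities of all tables (with the observed
    margins) no more likely than the observed one.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise StatsError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = _hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(1.0, p)


def significance_stars(p: float) -> str:
    """Boxplot-style significance annotation at 0.05/0.01/0.001/0.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
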