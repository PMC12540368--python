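"""Shared statistical primitives.

Houses the nonparametric machinery used across the pipeline: the
Wilcoxon rank-sum test (exact enumeration for small groups, tie-corrected
normal approximation otherwise), Kruskal-Wallis, Spearman correlation,
Benjamini-Hochberg adjustment, and Hartigan's dip test of unimodality
(statistic plus Monte-Carlo p-value under the uniform null).
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rank_sum_test",
    "kruskal_test",
    "spearman_corr",
    "benjamini_hochberg",
    "dip_statistic",
    "dip_pvalue",
]

# largest number of labelings we are willing to enumerate for an exact
# rank-sum p-value; C(16, 8) = 12870 sits well inside this
_EXACT_ENUM_LIMIT = 200_000


def _exact_rank_sum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating all group labelings.

    Mid-ranks are used, so ties are handled exactly. The two-sided p is
    twice the smaller tail of the permutation distribution of the
    rank sum of the first group, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = pooled.size
    n1 = x.size
    w_obs = ranks[:n1].sum()
    k = min(n1, n - n1)
    total = math.comb(n, k)
    if total > _EXACT_ENUM_LIMIT:
        raise ValueError(
            f"exact enumeration infeasible: C({n},{k}) = {total} labelings"
        )
    # enumerate rank sums of the *smaller* group; translate the observed
    # statistic onto that group if needed
    rank_total = ranks.sum()
    w_small_obs = w_obs if k == n1 else rank_total - w_obs
    le = 0
    ge = 0
    for idx in combinations(range(n), k):
        w = ranks[list(idx)].sum()
        if w <= w_small_obs + 1e-9:
            le += 1
        if w >= w_small_obs - 1e-9:
            ge += 1
    p = 2.0 * min(le, ge) / total
    return min(1.0, p)


def rank_sum_test(
    x,
    y,
    *,
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    Returns ``(statistic, p_value)`` where the statistic is the
    Mann-Whitney U of the first sample. When the smaller group has at
    most ``exact_max_n`` observations and full enumeration is tractable
    the p-value is exact (mid-rank ties handled by enumeration);
    otherwise the tie-corrected normal approximation with continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    u = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    stat = float(u.statistic)
    n = x.size + y.size
    k = min(x.size, y.size)
    if k <= exact_max_n and math.comb(n, k) <= _EXACT_ENUM_LIMIT:
        return stat, _exact_rank_sum_pvalue(x, y)
    return stat, float(u.pvalue)


def kruskal_test(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H-test across two or more groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    stat, p = sps.kruskal(*groups)
    return float(stat), float(p)


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks and t-approximation p.

    Constant input yields ``(nan, nan)`` with a warning rather than an
    exception, mirroring how a degenerate score vector should surface.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Hartigan dip test
# ---------------------------------------------------------------------------
#
# dip(F_n) = min over unimodal CDFs G of sup_x |F_n(x) - G(x)|, where
# "unimodal" means convex up to a mode and concave beyond it (an atom at
# the mode is allowed).  The computation alternates between the greatest
# convex minorant (gcm) and least concave majorant (lcm) of the empirical
# CDF on a shrinking modal interval: the answer is half the largest
# vertical discrepancy (in counts) that cannot be attributed to the
# convex or concave flanks.  Validated against an exact linear-program
# oracle on small samples (see the test suite).


def _lower_hull(xs: np.ndarray, ys: np.ndarray) -> list[int]:
    """Indices of the lower convex hull of a set of points with strictly
    increasing x."""
    hull: list[int] = []
    for i in range(len(xs)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # pop b if it lies on or above the chord a->i
            if (ys[b] - ys[a]) * (xs[i] - xs[a]) >= (ys[i] - ys[a]) * (xs[b] - xs[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def _upper_hull(xs: np.ndarray, ys: np.ndarray) -> list[int]:
    hull: list[int] = []
    for i in range(len(xs)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (ys[b] - ys[a]) * (xs[i] - xs[a]) <= (ys[i] - ys[a]) * (xs[b] - xs[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def _interp_on_hull(xs, ys, hull, query_x):
    """Piecewise-linear interpolation along hull vertices."""
    hx = xs[hull]
    hy = ys[hull]
    return np.interp(query_x, hx, hy)


def dip_statistic(x) -> float:
    """Hartigan's dip statistic of a 1-d sample.

    Returns the sup-distance from the empirical CDF to the nearest
    unimodal CDF.  Degenerate samples (n < 2 or all values identical)
    return 0.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0

    # collapse ties: per unique value, the ecdf count just below it and
    # the count at/after it
    xu, first, counts = np.unique(x, return_index=True, return_counts=True)
    lo_cnt = first.astype(float)
    hi_cnt = (first + counts).astype(float)
    m = xu.size
    if m == 1:  # pragma: no cover - guarded above
        return 0.0

    low, high = 0, m - 1
    best = 1.0  # counts; the floor corresponds to dip >= 1/(2n)

    while True:
        sl = slice(low, high + 1)
        xs = xu[sl]
        gcm = _lower_hull(xs, lo_cnt[sl])
        lcm = _upper_hull(xs, hi_cnt[sl])
        gcm_idx = [low + i for i in gcm]
        lcm_idx = [low + i for i in lcm]

        # largest vertical gap between the two hulls, tracked with the
        # candidate modal interval it defines
        d = -np.inf
        ig, ih = low, high
        lcm_at_g = _interp_on_hull(xs, hi_cnt[sl], lcm, xu[gcm_idx])
        for j, gi in enumerate(gcm_idx):
            gap = lcm_at_g[j] - lo_cnt[gi]
            if gap > d:
                d = gap
                ig = gi
                # first lcm vertex at or right of the gcm touch point
                ih = lcm_idx[-1]
                for li in lcm_idx:
                    if li >= gi:
                        ih = li
                        break
        gcm_at_l = _interp_on_hull(xs, lo_cnt[sl], gcm, xu[lcm_idx])
        for j, li in enumerate(lcm_idx):
            gap = hi_cnt[li] - gcm_at_l[j]
            if gap > d:
                d = gap
                ih = li
                ig = li
                for gi in reversed(gcm_idx):
                    if gi <= li:
                        ig = gi
                        break

        if d <= best:
            break

        # deviation of the ecdf above the gcm on the convex flank
        flank = np.arange(low, ig + 1)
        if flank.size:
            gline = _interp_on_hull(xs, lo_cnt[sl], gcm, xu[flank])
            dip_l = float(np.max(hi_cnt[flank] - gline))
        else:  # pragma: no cover
            dip_l = 0.0
        # deviation of the ecdf below the lcm on the concave flank
        flank = np.arange(ih, high + 1)
        if flank.size:
            lline = _interp_on_hull(xs, hi_cnt[sl], lcm, xu[flank])
            dip_u = float(np.max(lline - lo_cnt[flank]))
        else:  # pragma: no cover
            dip_u = 0.0

        best = max(best, dip_l, dip_u)
        if low == ig and high == ih:
            break
        low, high = ig, ih

    return best / (2.0 * n)


def dip_pvalue(x, n_boot: int = 200, seed: int = 0) -> tuple[float, float]:
    """Dip test of unimodality.

    Returns ``(dip, p)`` where p is calibrated by Monte-Carlo simulation
    of ``n_boot`` uniform samples of the same size (the classical null
    for the dip test).  Small p indicates multimodality.
    """
    x = np.asarray(x, dtype=float)
    d_obs = dip_statistic(x)
    rng = np.random.default_rng(seed)
    n = x.size
    exceed = 0
    for _ in range(n_boot):
        d0 = dip_statistic(rng.uniform(size=n))
        if d0 >= d_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_boot)
    return d_obs, p
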