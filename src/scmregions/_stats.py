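"""Shared statistical primitives: rank-sum tests, BH adjustment, one-sided Fisher.

The rank-sum test is the workhorse of every differential-expression step, so it
gets an exact small-sample path (full enumeration of rank arrangements, midranks
for ties) and a vectorised tie-corrected normal approximation for everything
else.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

# Exact enumeration is used when the number of group-label arrangements is at
# most this; C(20,10)=184756 already exceeds it, so routine DE uses the
# approximation while toy examples are exact.
EXACT_MAX_ARRANGEMENTS = 20_000


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact when the number of arrangements C(n, n_x) is small enough, handling
    ties through midranks; otherwise a tie-corrected normal approximation with
    continuity correction.  Returns ``(rank_sum_of_x, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    t_obs = float(ranks[:nx].sum())
    mu = nx * (nx + ny + 1) / 2.0

    if comb(nx + ny, nx) <= EXACT_MAX_ARRANGEMENTS:
        # The rank-sum distribution over arrangements is symmetric about mu
        # (complement reflection), so two-sided p = P(|T - mu| >= |t - mu|).
        dev = abs(t_obs - mu) - 1e-12
        n_extreme = 0
        total = 0
        for idx in combinations(range(nx + ny), nx):
            t = ranks[list(idx)].sum()
            total += 1
            if abs(t - mu) >= dev:
                n_extreme += 1
        return t_obs, n_extreme / total

    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return t_obs, 1.0
    z = (abs(t_obs - mu) - 0.5) / np.sqrt(var)
    return t_obs, float(min(1.0, 2.0 * stats.norm.sf(z)))


def rank_sum_test_matrix(X, Y) -> np.ndarray:
    """Two-sided tie-corrected rank-sum p-values, one per column.

    ``X`` (n_x, m) vs ``Y`` (n_y, m).  Columns with zero pooled variance
    (every value identical) get p = 1.  Tiny group sizes fall back to the
    exact enumeration of :func:`rank_sum_test`, column by column.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if comb(len(X) + len(Y), len(X)) <= EXACT_MAX_ARRANGEMENTS:
        return np.array([rank_sum_test(X[:, j], Y[:, j])[1] for j in range(X.shape[1])])
    res = stats.mannwhitneyu(
        X, Y, axis=0, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    p = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
    degenerate = np.ptp(np.vstack([X, Y]), axis=0) == 0
    p[degenerate | ~np.isfinite(p)] = 1.0
    return np.minimum(p, 1.0)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Equivalent to the upper hypergeometric tail P(X >= a) with population
    a+b+c+d, a+c successes and a+b draws.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("table entries must be non-negative")
    # hypergeom.sf is numerically stable for large tables; fisher_exact would
    # do the same sum term-by-term.
    n_pop = a + b + c + d
    return float(stats.hypergeom.sf(a - 1, n_pop, a + c, a + b))


def kruskal_p(groups) -> float:
    """Kruskal-Wallis p across >= 2 groups; p = 1 when every value is equal."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        return 1.0
    return float(stats.kruskal(*groups).pvalue)
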