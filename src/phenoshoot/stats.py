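"""Nonparametric group statistics: Mann–Whitney U, Spearman, quartiles.

Two-group comparisons use the Mann–Whitney U test (exact null enumeration
for small tie-free samples, normal approximation with tie and continuity
corrections otherwise); monotone association uses the Spearman rank
correlation with a permutation p value.  Summaries are medians with lower
and upper quartiles, computed by a named interpolation rule so outputs are
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sps

QUARTILE_RULE = "linear"  # numpy's linear interpolation between closest ranks

#: exact Mann–Whitney enumeration is used when n1*n2 is at most this and no ties
EXACT_MW_LIMIT = 400

#: Spearman permutation p is exact for n <= this, Monte-Carlo beyond
EXACT_SPEARMAN_N = 8


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> StatResult:
    """Two-sided Mann–Whitney U test.

    The statistic is U of the first sample (rank sums with midrank ties).
    The null distribution is enumerated exactly when ``n1*n2 <= 400`` and
    the pooled sample is tie-free; otherwise the normal approximation with
    tie correction and continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = a.size * b.size <= EXACT_MW_LIMIT and not ties
    res = sps.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return StatResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=a.size,
        n2=b.size,
        method="exact" if exact else "normal_approx",
    )


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman(
    x: np.ndarray,
    y: np.ndarray,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> StatResult:
    """Spearman rank correlation with a two-sided permutation p value.

    rho is the Pearson correlation of midranks.  The p value enumerates all
    permutations of one argument for n <= 8 and uses seeded Monte-Carlo
    resampling otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("rho undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_corr(rx, ry)

    n = x.size
    tol = 1e-12
    if n <= EXACT_SPEARMAN_N:
        count = total = 0
        for perm in permutations(ry):
            total += 1
            if abs(_rank_corr(rx, np.asarray(perm))) >= abs(rho) - tol:
                count += 1
        p = count / total
        method = "exact"
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_resamples):
            if abs(_rank_corr(rx, rng.permutation(ry))) >= abs(rho) - tol:
                count += 1
        p = (count + 1) / (n_resamples + 1)
        method = "monte_carlo"
    return StatResult(statistic=rho, p_value=p, n1=n, n2=n, method=method)


def median_quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """(Q1, median, Q3) under the linear-interpolation quantile rule.

    The rule name is exposed as :data:`QUARTILE_RULE` and recorded in all
    summary tables the package writes.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75], method=QUARTILE_RULE)
    return float(q1), float(med), float(q3)
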