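"""Nonparametric group statistics: exact Wilcoxon signed-rank, Friedman
with Tukey–Kramer follow-ups, and ICC helpers.

The Wilcoxon test enumerates the exact null for small samples: zero
differences are dropped, tied absolute differences get midranks, W is the
sum of positive ranks, and the two-sided p doubles the smaller tail of the
exact distribution over all 2ⁿ sign assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = ["WilcoxonResult", "wilcoxon_exact", "friedman_test"]


@dataclass
class WilcoxonResult:
    W: float
    p: float
    n: int  # non-zero differences used
    exact: bool


def _signed_ranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    nz = d[d != 0]
    ranks = sstats.rankdata(np.abs(nz))  # midranks for ties
    return nz, ranks


def _exact_tail_cdf(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of W (sum of positive ranks) over all 2ⁿ sign
    assignments, via subset-sum counting on doubled (integer) ranks.

    Returns (support, pmf) on the doubled-rank scale.
    """
    r2 = np.round(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    pmf = counts / counts.sum()
    return np.arange(total + 1), pmf


def wilcoxon_exact(
    differences: np.ndarray, null_value: float = 0.0, exact_limit: int = 25
) -> WilcoxonResult:
    """One-sample Wilcoxon signed-rank test of ``differences`` against
    ``null_value``.

    For n ≤ ``exact_limit`` non-zero differences the two-sided p-value is
    exact: 2·P(W′ ≤ min(W, Wmax − W)) under enumeration of every sign
    assignment (midranks for ties).  Larger samples fall back to the normal
    approximation with tie correction and are flagged ``exact=False``.
    """
    d = np.asarray(differences, float) - null_value
    nz, ranks = _signed_ranks(d)
    n = len(nz)
    if n == 0:
        raise ValueError("all differences equal the null value; W undefined")
    W = float(ranks[nz > 0].sum())
    wmax = float(ranks.sum())
    if n <= exact_limit:
        support, pmf = _exact_tail_cdf(ranks)
        w2 = np.round(2 * min(W, wmax - W)).astype(int)
        p = 2.0 * float(pmf[support <= w2].sum())
        return WilcoxonResult(W=W, p=min(p, 1.0), n=n, exact=True)
    mu = wmax / 2.0
    # variance with midrank tie correction: sum of squared ranks / 4
    sigma = np.sqrt(np.sum(ranks**2) / 4.0)
    z = (W - mu) / sigma
    p = 2.0 * sstats.norm.sf(abs(z))
    return WilcoxonResult(W=W, p=min(p, 1.0), n=n, exact=False)


def friedman_test(values: np.ndarray) -> dict:
    """Friedman test across conditions (columns) over subjects (rows), with
    Tukey–Kramer corrected rank-based pairwise follow-ups.

    Pairwise comparisons use the studentized-range distribution on the mean
    rank differences: q = |R̄_i − R̄_j| / sqrt(k(k+1)/(12n)).
    """
    X = np.asarray(values, float)
    n, k = X.shape
    if k < 3:
        raise ValueError("Friedman test needs at least 3 conditions")
    ranks = np.apply_along_axis(sstats.rankdata, 1, X)
    mean_ranks = ranks.mean(axis=0)
    if np.allclose(X, X[:, [0]]):
        stat, p = 0.0, 1.0
    else:
        stat, p = sstats.friedmanchisquare(*[X[:, j] for j in range(k)])
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks[i] - mean_ranks[j]) / se
            # studentized range with infinite error df (large-sample Nemenyi)
            pq = float(sstats.studentized_range.sf(q * np.sqrt(2.0), k, 1e6))
            pairwise.append(
                {"i": i, "j": j, "mean_rank_diff": mean_ranks[i] - mean_ranks[j],
                 "q": q, "p": pq}
            )
    return {
        "statistic": float(stat),
        "p": float(p),
        "df": k - 1,
        "mean_ranks": mean_ranks,
        "pairwise": pairwise,
    }
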