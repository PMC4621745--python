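"""Shared statistical primitives: the rank-sum engine and FDR control.

One rank-sum implementation backs both the SCNA burden comparison and the
lesion-burden association tests, so every p-value in the pipeline has the
same tie handling: exact enumeration over all group assignments when both
groups have at most ``EXACT_MAX`` values, and the tie-corrected normal
approximation (with continuity correction) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_MAX = 8  # exact enumeration when both groups are at most this size

_EPS = 1e-9  # float tolerance when comparing midrank sums


@dataclass(frozen=True)
class RankSumResult:
    """Two-sample Wilcoxon-Mann-Whitney result.

    ``p_greater`` / ``p_less`` are the fixed-direction one-sided tails
    (first group ranking higher / lower); a calibrated one-sided test uses
    one of these, chosen a priori.  ``p_one`` is the tail in the direction
    of the observed shift (the number conventionally quoted next to a
    directed finding); under the null it is not uniform, being a min of two
    tails.  ``direction`` is +1 when the first group ranks higher, -1 when
    it ranks lower, 0 at the exact null expectation.
    """

    statistic: float  # rank sum W of the first group (midranks)
    n_x: int
    n_y: int
    p_two: float
    p_greater: float
    p_less: float
    direction: int
    exact: bool

    @property
    def p_one(self) -> float:
        return min(self.p_greater, self.p_less)


def rank_sum_test(x, y) -> RankSumResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test requires two non-empty groups")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[: x.size].sum())
    mu = x.size * (pooled.size + 1) / 2.0
    direction = 0 if abs(w_obs - mu) < _EPS else (1 if w_obs > mu else -1)

    if x.size <= EXACT_MAX and y.size <= EXACT_MAX:
        p_greater, p_less = _exact_tails(ranks, x.size, w_obs)
        exact = True
    else:
        p_greater = stats.mannwhitneyu(x, y, alternative="greater",
                                       method="asymptotic").pvalue
        p_less = stats.mannwhitneyu(x, y, alternative="less",
                                    method="asymptotic").pvalue
        exact = False
    p_two = float(min(1.0, 2.0 * min(p_greater, p_less)))
    return RankSumResult(w_obs, x.size, y.size, p_two, float(p_greater),
                         float(p_less), direction, exact)


def _exact_tails(ranks: np.ndarray, n_x: int, w_obs: float) -> tuple[float, float]:
    """Exact tail probabilities of the rank sum by enumerating all
    C(n, n_x) assignments of the pooled (mid)ranks to the first group."""
    n = ranks.size
    total = comb(n, n_x)
    ge = le = 0
    for idx in combinations(range(n), n_x):
        w = ranks[list(idx)].sum()
        if w >= w_obs - _EPS:
            ge += 1
        if w <= w_obs + _EPS:
            le += 1
    return ge / total, le / total


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]
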