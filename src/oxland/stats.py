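"""Shared statistical helpers."""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps


def rank_sum_test(x, y, exact_max_n: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Small samples (total n <= ``exact_max_n``) are enumerated exhaustively on
    the tie-averaged ranks; larger samples use the normal approximation with
    tie correction (scipy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n, m = len(x), len(y)
    total = n + m
    if total <= exact_max_n:
        ranks = sps.rankdata(np.concatenate([x, y]))
        w_obs = ranks[:n].sum()
        mu = n * (total + 1) / 2.0
        d_obs = abs(w_obs - mu)
        count = 0
        n_comb = 0
        for idx in combinations(range(total), n):
            w = ranks[list(idx)].sum()
            if abs(w - mu) >= d_obs - 1e-9:
                count += 1
            n_comb += 1
        return count / n_comb
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)
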