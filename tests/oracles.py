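"""Independent brute-force recomputations used as test oracles.

These deliberately re-derive each statistic step by step from its
definitional formula with plain Python loops, independent of the package
implementation they are checked against.
"""

import math

import numpy as np
from scipy import stats


def kendalls_w_bruteforce(ratings: np.ndarray, tie_correction: bool = True) -> float:
    """W = 12 S / (m^2 (n^3 - n) - m * sum_i T_i), S from column rank sums."""
    m, n = ratings.shape
    ranks = np.vstack([stats.rankdata(row) for row in ratings])
    column_sums = [sum(ranks[i][j] for i in range(m)) for j in range(n)]
    mean_sum = sum(column_sums) / n
    s = sum((r - mean_sum) ** 2 for r in column_sums)
    denom = m * m * (n**3 - n)
    if tie_correction:
        tie_term = 0.0
        for row in ratings:
            for value in set(row):
                t = list(row).count(value)
                tie_term += t**3 - t
        denom -= m * tie_term
    return 12.0 * s / denom


def entropy_weights_bruteforce(normalized: np.ndarray):
    """Stepwise proportions -> entropy -> redundancy -> weights."""
    n, m = normalized.shape
    k = 1.0 / math.log(n)
    entropies = []
    for j in range(m):
        column = normalized[:, j]
        total = sum(column)
        if total == 0:
            entropies.append(1.0)
            continue
        acc = 0.0
        for x in column:
            p = x / total
            if p > 0:
                acc += p * math.log(p)
        entropies.append(-k * acc)
    redundancies = [1.0 - e for e in entropies]
    total_d = sum(redundancies)
    return np.array(entropies), np.array([d / total_d for d in redundancies])


def minmax_normalize_bruteforce(raw: np.ndarray, directions) -> np.ndarray:
    out = np.empty_like(raw, dtype=float)
    n, m = raw.shape
    for j in range(m):
        lo = min(raw[:, j])
        hi = max(raw[:, j])
        for i in range(n):
            if directions[j] == "positive":
                out[i, j] = (raw[i, j] - lo) / (hi - lo)
            else:
                out[i, j] = (hi - raw[i, j]) / (hi - lo)
    return out
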