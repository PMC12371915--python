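"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths (and, where possible, the libraries)
they are checking.
"""

from itertools import combinations

import numpy as np


def bh_stepup(p):
    """Benjamini-Hochberg step-up from the textbook definition.

    adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1, mapped back to the
    input order.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        adj_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _u_statistic(x, y):
    """Mann-Whitney U of sample x (ties get half counts)."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def mann_whitney_exact(x, y):
    """Two-sided exact Mann-Whitney p by enumeration of all splits."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = _u_statistic(x, y)
    idx = range(len(pooled))
    count = 0
    total = 0
    mu = n1 * len(y) / 2.0
    for comb in combinations(idx, n1):
        sel = np.zeros(len(pooled), bool)
        sel[list(comb)] = True
        u = _u_statistic(pooled[sel], pooled[~sel])
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def kruskal_permutation(groups):
    """Exact permutation p of the Kruskal-Wallis H over all label splits."""
    from scipy.stats import rankdata

    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = rankdata(pooled)

    def h_stat(parts):
        h = 0.0
        for part in parts:
            h += part.sum() ** 2 / len(part)
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        # tie correction
        _, counts = np.unique(pooled, return_counts=True)
        tie = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
        return h / tie if tie > 0 else 0.0

    def splits(idx, sizes):
        if len(sizes) == 1:
            yield (tuple(idx),)
            return
        for comb in combinations(idx, sizes[0]):
            rest = [i for i in idx if i not in set(comb)]
            for tail in splits(rest, sizes[1:]):
                yield (comb,) + tail

    obs = h_stat([ranks[i:j] for i, j in
                  zip(np.cumsum([0] + sizes)[:-1], np.cumsum(sizes))])
    count = total = 0
    for assignment in splits(list(range(n)), sizes):
        parts = [ranks[list(g)] for g in assignment]
        total += 1
        if h_stat(parts) >= obs - 1e-12:
            count += 1
    return count / total


def pearson_r(a, b):
    """Pearson correlation straight from the definition."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    da, db = a - a.mean(), b - b.mean()
    return float((da * db).sum() / np.sqrt((da ** 2).sum() * (db ** 2).sum()))


def binomial_99ci(p, n):
    """Normal-approximation 99% interval for a proportion."""
    half = 2.5758 * np.sqrt(p * (1 - p) / n)
    return p - half, p + half
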