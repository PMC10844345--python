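"""Independent reference implementations used as test oracles.

These are written directly from textbook definitions and deliberately share
no code path with the package: per-judge ranking loops, manual Pearson
formulas per seed/window, and the literal step-up rule.
"""

import numpy as np
from scipy.stats import rankdata


def brute_force_w(values):
    """Tie-corrected Kendall's W from the rank definitions, judge by judge."""
    k, n = values.shape
    ranks = np.array([rankdata(row) for row in values])
    r = ranks.sum(axis=0)
    s = ((r - k * (n + 1) / 2.0) ** 2).sum()
    t_corr = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        t_corr += float((counts ** 3 - counts).sum())
    denom = k ** 2 * (n ** 3 - n) / 12.0 - k * t_corr / 12.0
    return s / denom if denom > 0 else np.nan


def naive_vertex_stability(data, tr, window_s, step_s):
    """O(V^2 W) vertex-by-vertex stability from first principles.

    For each seed vertex: per window, Pearson r with every other vertex from
    the covariance formula; then the textbook W of the window x target grid.
    """
    w = int(round(window_s / tr))
    s = int(round(step_s / tr))
    wins = []
    start = 0
    while start + w <= data.shape[1]:
        wins.append((start, start + w))
        start += s
    v = data.shape[0]
    out = np.empty(v)
    for seed in range(v):
        others = np.array([t for t in range(v) if t != seed])
        corr = np.empty((len(wins), v - 1))
        for wi, (a, b) in enumerate(wins):
            x = data[seed, a:b]
            x = x - x.mean()
            y = data[others, a:b]
            y = y - y.mean(axis=1, keepdims=True)
            corr[wi] = (y @ x) / np.sqrt((x @ x) * (y * y).sum(axis=1))
        out[seed] = brute_force_w(corr)
    return out


def brute_force_bh(p, q):
    """Benjamini-Hochberg step-up applied literally to the sorted p-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    sorted_p = p[order]
    thresh = q * (np.arange(m) + 1) / m
    below = np.flatnonzero(sorted_p <= thresh)
    reject = np.zeros(m, bool)
    if below.size:
        reject[order[: below.max() + 1]] = True
    adj = np.minimum.accumulate((sorted_p * m / (np.arange(m) + 1))[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj, 1.0)
    return reject, adjusted
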