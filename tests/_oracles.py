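"""Independent brute-force oracles used only by the test suite.

Everything here is written as an unvectorized, from-the-definition
transcription so it shares no code path with the package implementation.
"""

from __future__ import annotations

import math
from itertools import combinations


def midranks(vals):
    """Average-tie ranks (1-based), pure Python."""
    n = len(vals)
    order = sorted(range(n), key=lambda i: vals[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and vals[order[j + 1]] == vals[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_factors_oracle(matrix, trim_m=0.30, trim_a=0.05):
    """Trimmed-weighted-mean-of-M normalization factors, loop by loop.

    ``matrix`` is a list of feature rows (each a list of per-sample counts).
    Returns factors rescaled to geometric mean 1.
    """
    n_feat = len(matrix)
    n_samp = len(matrix[0])
    lib = [sum(matrix[i][k] for i in range(n_feat)) for k in range(n_samp)]
    uq = []
    for k in range(n_samp):
        scaled = sorted(matrix[i][k] / lib[k] for i in range(n_feat))
        h = 0.75 * (n_feat - 1)  # linear-interpolation quantile
        lo, hi = math.floor(h), math.ceil(h)
        uq.append(scaled[lo] + (h - lo) * (scaled[hi] - scaled[lo]))
    mean_uq = sum(uq) / n_samp
    ref = min(range(n_samp), key=lambda k: abs(uq[k] - mean_uq))
    factors = []
    for k in range(n_samp):
        m, a, w = [], [], []
        for i in range(n_feat):
            o, r = matrix[i][k], matrix[i][ref]
            if o > 0 and r > 0:
                m.append(math.log2((o / lib[k]) / (r / lib[ref])))
                a.append(0.5 * math.log2((o / lib[k]) * (r / lib[ref])))
                w.append(1.0 / ((lib[k] - o) / (lib[k] * o)
                                + (lib[ref] - r) / (lib[ref] * r)))
        if len(m) < 2 or max(abs(v) for v in m) < 1e-6:
            factors.append(1.0)
            continue
        n = len(m)
        rm = midranks(m)
        ra = midranks(a)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += w[i] * m[i]
                den += w[i]
        factors.append(2.0 ** (num / den) if den > 0 else 1.0)
    gm = math.exp(sum(math.log(f) for f in factors) / n_samp)
    return [f / gm for f in factors]


def mw_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration (tie-free data).

    Enumerates all C(n1+n2, n1) relabelings of the pooled values; returns
    (U of x, p) with the doubled-smaller-tail convention capped at 1.
    """
    pooled = list(x) + list(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(x)

    def ustat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = ustat(x, y)
    us = []
    idx = range(len(pooled))
    for comb in combinations(idx, n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in comb]
        us.append(ustat(xs, ys))
    total = len(us)
    cdf = sum(1 for u in us if u <= u_obs) / total
    sf = sum(1 for u in us if u >= u_obs) / total
    return u_obs, min(1.0, 2.0 * min(cdf, sf))


def hypergeom_upper_tail_oracle(k, K, n, N):
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact integer enumeration."""
    if k == 0:
        return 1.0
    num = 0
    for i in range(k, min(K, n) + 1):
        num += math.comb(K, i) * math.comb(N - K, n - i)
    return num / math.comb(N, n)


def bh_oracle(p):
    """Step-up Benjamini-Hochberg from the definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return adj


def spearman_oracle(x, y):
    """Spearman as Pearson on midranks, pure Python."""
    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    sxx = sum((a - mx) ** 2 for a in rx)
    syy = sum((b - my) ** 2 for b in ry)
    return sxy / math.sqrt(sxx * syy)


def auc_rank_oracle(scores, labels):
    """AUC as the pair-counting U statistic with half credit for ties."""
    pos = [s for s, t in zip(scores, labels) if t == 1]
    neg = [s for s, t in zip(scores, labels) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
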