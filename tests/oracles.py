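"""Independent brute-force oracles used to pin down the fast implementations.

Everything here is written as directly as possible from the definitions
(explicit loops, O(n^2) scans) and deliberately shares no code with the
package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_template_counts(x, m, r):
    """Unordered-pair template match counts for sample entropy."""
    x = list(map(float, x))
    n = len(x)
    b = a = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if all(abs(x[i + k] - x[j + k]) <= r for k in range(m)):
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return b, a


def brute_cosen(x, m=1, r=30.0):
    b, a = brute_template_counts(x, m, r)
    if a == 0 or b == 0:
        return math.nan
    mean = sum(x) / len(x)
    return -math.log(a / b) + math.log(2 * r) - math.log(mean)


def brute_neighbor_counts(x, r):
    """Per-point neighbor counts of the (RRI_i, RRI_{i+1}) embedding."""
    pts = [(x[i], x[i + 1]) for i in range(len(x) - 1)]
    counts = []
    for i, p in enumerate(pts):
        c = 0
        for j, q in enumerate(pts):
            if i != j and max(abs(p[0] - q[0]), abs(p[1] - q[1])) <= r:
                c += 1
        counts.append(c)
    return counts


def brute_dfa_f2(x, scale):
    """Mean squared residual of box-wise linear detrending at one scale."""
    x = np.asarray(x, dtype=float)
    y = np.cumsum(x - x.mean())
    k = len(y) // scale
    residuals = []
    for b in range(k):
        seg = y[b * scale:(b + 1) * scale]
        t = np.arange(scale, dtype=float)
        slope, intercept = np.polyfit(t, seg, 1)
        residuals.extend(seg - (slope * t + intercept))
    return float(np.mean(np.square(residuals)))


def brute_filter_rri(x, lo=250.0, hi=2000.0, rlo=0.6, rhi=1.8):
    """Sequential plausibility filter, literal greedy implementation."""
    out = []
    prev = None
    for v in x:
        if not (lo <= v <= hi):
            continue
        if prev is not None and not (rlo <= v / prev <= rhi):
            continue
        out.append(float(v))
        prev = v
    return out


def brute_auc(scores, labels):
    """Exhaustive case/control pair counting, ties counted 1/2."""
    cases = [s for s, y in zip(scores, labels) if y]
    ctrls = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for c in cases:
        for d in ctrls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(ctrls))


def brute_signed_rank_stat(diffs):
    """Wilcoxon signed-rank W+ (zeros dropped, mid-ranks for ties)."""
    d = [x for x in diffs if x != 0]
    absd = sorted((abs(x), i) for i, x in enumerate(d))
    ranks = [0.0] * len(d)
    i = 0
    while i < len(absd):
        j = i
        while j < len(absd) and absd[j][0] == absd[i][0]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[absd[k][1]] = mid
        i = j
    return sum(r for r, x in zip(ranks, d) if x > 0)


def brute_signed_rank_p_greater(diffs):
    """Exact one-sided p-value by enumerating all sign assignments."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    w_obs = brute_signed_rank_stat(d)
    absd = [abs(x) for x in d]
    count = 0
    for signs in itertools.product([1, -1], repeat=n):
        w = brute_signed_rank_stat([s * a for s, a in zip(signs, absd)])
        if w >= w_obs:
            count += 1
    return count / 2 ** n


def brute_rank_sum_p(a, b):
    """Exact two-sided rank-sum p-value by enumerating group assignments."""
    pooled = list(a) + list(b)
    n, m = len(a), len(b)

    def u_stat(group_a):
        u = 0.0
        rest = list(pooled)
        ga = list(group_a)
        for x in ga:
            rest.remove(x)
        for x in ga:
            for y in rest:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    u_obs = u_stat(a)
    mu = n * m / 2.0
    count = total = 0
    for comb in itertools.combinations(range(n + m), n):
        u = u_stat([pooled[i] for i in comb])
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total
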