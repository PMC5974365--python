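"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — enumeration, per-bp loops,
transitive closure — and shares no code with the implementation it
checks.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def binom_two_sided_p(k: int, n: int, p: float) -> float:
    """Exact two-sided binomial p-value by full tail enumeration.

    Sums P(X = j) over all j whose point probability does not exceed
    that of the observed k (the minimum-likelihood definition).
    """
    pmf = [math.comb(n, j) * p**j * (1 - p) ** (n - j)
           for j in range(n + 1)]
    cut = pmf[k] * (1 + 1e-10)
    return min(sum(q for q in pmf if q <= cut), 1.0)


def bh_stepup_q(pvals) -> np.ndarray:
    """Benjamini-Hochberg q-values by the textbook step-up recursion."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q_sorted[rank - 1] = running
    q = np.empty(n)
    q[order] = q_sorted
    return q


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Fisher exact p by hypergeometric enumeration of all tables."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def table_p(x):
        return (math.comb(row1, x) * math.comb(row2, col1 - x)
                / math.comb(n, col1))

    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    obs = table_p(a)
    return min(sum(table_p(x) for x in range(lo, hi + 1)
                   if table_p(x) <= obs * (1 + 1e-10)), 1.0)


def mannwhitney_two_sided_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    Valid for small, tie-free samples: doubles the smaller tail of the
    permutation distribution of U.
    """
    x, y = list(x), list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n = len(x)

    def u_stat(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi)

    u_obs = u_stat(x, y)
    us = [u_stat(combo, [v for v in pooled if v not in combo])
          for combo in itertools.combinations(pooled, n)]
    us = np.array(us)
    p_lo = np.mean(us <= u_obs)
    p_hi = np.mean(us >= u_obs)
    return float(min(2 * min(p_lo, p_hi), 1.0))


def transitive_closure_clusters(intervals, gap: int):
    """O(n^2) single-linkage clustering of (start, end) intervals.

    Two reads link when the gap between them (0 if they overlap) is
    strictly below ``gap``; clusters are connected components.
    Returns a list of sorted member-index lists.
    """
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            s1, e1 = intervals[i]
            s2, e2 = intervals[j]
            dist = max(s2 - e1, s1 - e2, 0)
            if dist < gap:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted((sorted(g) for g in groups.values()),
                  key=lambda g: g[0])


def metagene_bins_bruteforce(sites, features, flank, body_bins,
                             flank_bins):
    """Per-bin pooled counts by a plain per-site/per-feature loop.

    ``sites`` rows: (contig, pos0, meth, unmeth); ``features`` rows:
    (contig, start, end, strand).  Returns (meth, total) arrays.
    """
    total_bins = 2 * flank_bins + body_bins
    meth = np.zeros(total_bins)
    total = np.zeros(total_bins)
    w = flank / flank_bins
    for contig, start, end, strand in features:
        for c, pos, m, u in sites:
            if c != contig or not (start - flank <= pos < end + flank):
                continue
            if pos < start:
                idx = int((pos - (start - flank)) // w)
            elif pos >= end:
                idx = flank_bins + body_bins + int((pos - end) // w)
            else:
                idx = flank_bins + (pos - start) * body_bins // (end - start)
            if strand == "-":
                idx = total_bins - 1 - idx
            meth[idx] += m
            total[idx] += m + u
    return meth, total
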