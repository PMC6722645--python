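"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the overlap oracle is
an all-pairs scan, the Fisher oracle enumerates the hypergeometric PMF with
exact integer combinatorics, the BH oracle is the textbook step-up formula,
and the Spearman oracle ranks and then applies the raw Pearson sum formula.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

# Fraction is used where exactness matters more than speed
# (hypergeom_upper_tail); the PMF enumeration uses exact integer binomials
# with one float division per term.


def brute_force_overlap_pairs(regions, peaks, min_overlap=1, stranded=False):
    """All-pairs (region index, peak index) overlaps; the sweep's oracle."""
    pairs = set()
    for i, r in enumerate(regions):
        for j, p in enumerate(peaks):
            if r.chrom != p.chrom:
                continue
            if stranded and r.strand != p.strand:
                continue
            if min(r.end, p.end) - max(r.start, p.start) >= min_overlap:
                pairs.add((i, j))
    return pairs


def fisher_enumeration(x, y, a, b):
    """Exact one- and two-sided hypergeometric tail p-values for a 2x2 table.

    Enumerates the PMF over the full support with integer binomials; returns
    (p_greater, p_less, p_two_sided) as floats (exact rational -> float).
    """
    n1 = x + y
    k_total = x + a
    n = x + y + a + b
    lo = max(0, n1 - (n - k_total))
    hi = min(n1, k_total)
    denom = math.comb(n, n1)
    pmf = {
        k: math.comb(k_total, k) * math.comb(n - k_total, n1 - k) / denom
        for k in range(lo, hi + 1)
    }
    p_greater = min(1.0, sum(v for k, v in pmf.items() if k >= x))
    p_less = min(1.0, sum(v for k, v in pmf.items() if k <= x))
    cutoff = pmf[x] * (1.0 + 1e-7)
    p_two = min(1.0, sum(v for v in pmf.values() if v <= cutoff))
    return p_greater, p_less, p_two


def bh_step_up(pvalues):
    """Textbook Benjamini-Hochberg: adj_i = min_{k >= rank(i)} m * p_(k) / k."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        rank = pos + 1
        running_min = min(running_min, m * pvalues[i] / rank)
        adjusted[i] = min(1.0, running_min)
    return adjusted


def naive_spearman_distance(X):
    """Rank each row, then apply the raw Pearson sum formula pairwise."""
    X = np.asarray(X, dtype=float)
    n_rows, n = X.shape

    def rank(row):
        order = sorted(range(n), key=lambda i: row[i])
        ranks = [0.0] * n
        i = 0
        while i < n:
            j = i
            while j + 1 < n and row[order[j + 1]] == row[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    ranked = [rank(row) for row in X]
    dist = np.zeros((n_rows, n_rows))
    for i in range(n_rows):
        for j in range(n_rows):
            if i == j:
                continue
            u, v = ranked[i], ranked[j]
            mu = sum(u) / n
            mv = sum(v) / n
            cov = sum((a - mu) * (b - mv) for a, b in zip(u, v))
            su = math.sqrt(sum((a - mu) ** 2 for a in u))
            sv = math.sqrt(sum((b - mv) ** 2 for b in v))
            if su == 0 or sv == 0:
                dist[i, j] = 2.0
            else:
                dist[i, j] = 1.0 - cov / (su * sv)
    return dist


def hypergeom_upper_tail(k, n_universe, n_term, n_query):
    """P(overlap >= k) by direct combinatorial sum."""
    denom = math.comb(n_universe, n_query)
    total = Fraction(0)
    for i in range(k, min(n_term, n_query) + 1):
        total += Fraction(
            math.comb(n_term, i) * math.comb(n_universe - n_term, n_query - i), denom
        )
    return float(total)
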