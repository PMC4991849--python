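"""Independent, deliberately naive reference implementations used as test
oracles.  These are written from the textbook definitions and share no code
with the package."""

from __future__ import annotations

import itertools
import math

import numpy as np


def median_polish_sweep(X, n_sweeps=200, tol=1e-10):
    """Plain iterative row/column median sweep (no effect-median folding)."""
    R = np.array(X, dtype=float)
    nr, nc = R.shape
    row = np.zeros(nr)
    col = np.zeros(nc)
    for _ in range(n_sweeps):
        before = R.copy()
        for i in range(nr):
            m = np.median(R[i])
            R[i] -= m
            row[i] += m
        for j in range(nc):
            m = np.median(R[:, j])
            R[:, j] -= m
            col[j] += m
        if np.max(np.abs(R - before)) < tol:
            break
    grand = np.median(row)
    row = row - grand
    g2 = np.median(col)
    col = col - g2
    grand += g2
    return grand, row, col, R


def bh_stepup(pvalues, q):
    """Naive O(m^2) Benjamini-Hochberg step-up rejection set."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= rank * q / m:
            k_star = rank
    reject = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= k_star:
            reject[i] = True
    return reject


def best_contiguous_partition(values, k):
    """Exhaustive search over contiguous k-partitions of a (T, C) array;
    returns (min cost, boundary index tuple)."""
    E = np.asarray(values, dtype=float)
    if E.ndim == 1:
        E = E[:, None]
    T = E.shape[0]

    def seg_cost(i, j):
        seg = E[i:j]
        return float(((seg - seg.mean(axis=0)) ** 2).sum())

    best = (math.inf, None)
    for cuts in itertools.combinations(range(1, T), k - 1):
        bounds = (0,) + cuts + (T,)
        cost = sum(seg_cost(a, b) for a, b in zip(bounds, bounds[1:]))
        if cost < best[0]:
            best = (cost, cuts)
    return best


def sam_statistics(X, group2_cols, s0):
    """Textbook SAM d for one labeling: X genes x samples, group2_cols a
    boolean mask for the second group."""
    X = np.asarray(X, dtype=float)
    g2 = np.asarray(group2_cols, dtype=bool)
    g1 = ~g2
    n1, n2 = g1.sum(), g2.sum()
    m1, m2 = X[:, g1].mean(axis=1), X[:, g2].mean(axis=1)
    ss = ((X[:, g1] - m1[:, None]) ** 2).sum(axis=1) + \
         ((X[:, g2] - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2) * ss)
    return (m2 - m1) / (s + s0)


def sam_expected_order_stats(X, n1, s0):
    """Mean of sorted d over every distinct split of the columns (brute
    force enumeration, all C(n, n1) label assignments)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    acc = None
    count = 0
    for split in itertools.combinations(range(n), n1):
        g2 = np.ones(n, dtype=bool)
        g2[list(split)] = False
        d = np.sort(sam_statistics(X, g2, s0))
        acc = d if acc is None else acc + d
        count += 1
    return acc / count, count


def hypergeom_tail_enumeration(overlap, universe, size_a, size_b):
    """P(X >= overlap) by direct summation of combinatorial terms."""
    total = 0.0
    denom = math.comb(universe, size_b)
    for k in range(overlap, min(size_a, size_b) + 1):
        total += math.comb(size_a, k) * \
            math.comb(universe - size_a, size_b - k) / denom
    return total


def pearson_r(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))
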