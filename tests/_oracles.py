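"""Independent brute-force oracles used to validate the implementations.

Everything here is written from first principles (enumeration, exact
rational arithmetic) and deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, sqrt

import numpy as np
from scipy.special import ndtr, ndtri


def bc_bootstrap_ci_enumeration(values, conf):
    """Exact BC percentile bootstrap CI by enumerating all N^N resamples.

    Every resample of size N drawn with replacement is equiprobable, so the
    bootstrap distribution of the mean is the multiset of all N^N resample
    means. The bias-correction proportion and the quantiles are computed on
    that exact distribution. Quantiles use the discrete inverse CDF
    (``inverted_cdf``): that is the large-``n_boot`` limit of any empirical
    quantile of Monte-Carlo resample means, interpolation convention aside.
    """
    v = [float(x) for x in values]
    n = len(v)
    means = np.array([sum(t) / n for t in itertools.product(v, repeat=n)])
    observed = sum(v) / n
    p = np.count_nonzero(means < observed) / means.size
    p = min(max(p, 1.0 / (2 * means.size)), 1 - 1.0 / (2 * means.size))
    z0 = ndtri(p)
    za = ndtri((1 + conf) / 2)
    return (float(np.quantile(means, ndtr(2 * z0 - za), method="inverted_cdf")),
            float(np.quantile(means, ndtr(2 * z0 + za), method="inverted_cdf")))


def bc_bounds_agreement(vals, mc_bounds, conf):
    """Compare MC bootstrap bounds with the enumeration oracle.

    For N = 4 the bootstrap-mean distribution has at most 256 atoms whose
    values can sit further apart than any fixed tolerance, so finite-n_boot
    Monte-Carlo noise in the bias-correction term and in the empirical CDF
    occasionally selects an atom adjacent to the exact one. Agreement is
    therefore reported two ways per bound: the absolute value gap, and the
    number of distinct atoms strictly between the MC and exact bounds
    (0 = same or neighboring atom; a wrong implementation lands many atoms
    away).
    """
    exact = bc_bootstrap_ci_enumeration(vals, conf)
    v = [round(float(x), 12) for x in vals]
    atoms = np.unique(np.round([sum(t) / 4 for t in
                                itertools.product(v, repeat=4)], 12))
    out = []
    for mc_b, ex_b in zip(mc_bounds, exact):
        gap = abs(mc_b - ex_b)
        lo, hi = sorted((mc_b, ex_b))
        between = int(((atoms > lo + 1e-9) & (atoms < hi - 1e-9)).sum())
        out.append((gap, between))
    return out


def upgma_bruteforce(dist, labels):
    """Naive UPGMA recomputing every average from the original matrix.

    Clusters are frozensets of leaf indices; at each step the average
    cross-pair distance is recomputed from scratch for every cluster pair
    and the minimum merged (ties by the lexicographically smallest pair of
    sorted member-label tuples). Returns the cophenetic distance for every
    leaf pair (the merged average distance of their joining step).
    """
    d = np.asarray(dist, dtype=float)
    clusters = [frozenset([i]) for i in range(len(labels))]
    coph = {}

    def avg(a, b):
        return float(np.mean([d[i, j] for i in a for j in b]))

    def name(c):
        return tuple(sorted(str(labels[i]) for i in c))

    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            key = (avg(a, b), tuple(sorted((name(a), name(b)))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (dij, _), a, b = best
        for i in a:
            for j in b:
                pair = (str(labels[i]), str(labels[j]))
                coph[tuple(sorted(pair))] = dij
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return coph


def fisher_two_tailed_enumeration(a, b, c, d):
    """Two-tailed Fisher exact P in exact rational arithmetic.

    Enumerates every 2x2 table with the observed margins and sums the
    hypergeometric probabilities of tables no more probable than the
    observed one.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # P(first cell = x) under fixed margins
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs)
    return float(total)


def mann_whitney_exact_enumeration(x, y):
    """Exact two-tailed Mann-Whitney P by enumerating rank assignments.

    Requires tie-free data. U_x is the number of (x, y) pairs with x > y;
    the null distribution is obtained by assigning the pooled ranks to the
    first sample in every possible way. Two-tailed P doubles the smaller
    tail (capped at 1), the convention used for the exact test.
    """
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n, m = len(x), len(y)
    ranks = range(len(pooled))
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for positions in itertools.combinations(ranks, n):
        # U for a sample occupying these sorted-rank positions
        us.append(sum(p - k for k, p in enumerate(sorted(positions))))
    us = np.array(us)
    p_lo = np.count_nonzero(us <= u_obs) / us.size
    p_hi = np.count_nonzero(us >= u_obs) / us.size
    return u_obs, min(1.0, 2 * min(p_lo, p_hi))
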