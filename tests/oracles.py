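"""Brute-force reference implementations used to validate the package.

Everything here is deliberately naive (itertools over all tuples,
exhaustive recursion over sampling orders) so that correctness is
obvious by inspection; tests compare the fast package code against
these on small inputs.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def brute_simplex_list(A: np.ndarray, max_dim: int | None = None):
    """All directed simplices as vertex tuples, by checking every
    ordered tuple of distinct vertices for the all-pairs edge
    condition."""
    n = A.shape[0]
    out = [(v,) for v in range(n)]
    d = 1
    while max_dim is None or d <= max_dim:
        found = []
        for tup in itertools.permutations(range(n), d + 1):
            if all(A[tup[i], tup[j]] for i in range(d + 1) for j in range(i + 1, d + 1)):
                found.append(tup)
        if not found:
            break
        out.extend(found)
        d += 1
    return out


def brute_simplex_counts(A: np.ndarray, max_dim: int | None = None) -> list[int]:
    counts: dict[int, int] = {}
    for tup in brute_simplex_list(A, max_dim):
        counts[len(tup) - 1] = counts.get(len(tup) - 1, 0) + 1
    top = max(counts)
    return [counts.get(d, 0) for d in range(top + 1)]


def brute_is_maximal(A: np.ndarray, tup: tuple[int, ...]) -> bool:
    """A simplex is maximal iff no vertex can be inserted at any
    position to form a larger simplex."""
    n = A.shape[0]
    for w in range(n):
        if w in tup:
            continue
        for p in range(len(tup) + 1):
            cand = tup[:p] + (w,) + tup[p:]
            if all(A[cand[i], cand[j]]
                   for i in range(len(cand)) for j in range(i + 1, len(cand))):
                return False
    return True


def brute_maximal_simplices(A: np.ndarray):
    return [tup for tup in brute_simplex_list(A) if brute_is_maximal(A, tup)]


def brute_triad_census(A: np.ndarray) -> dict[str, int]:
    """Connected-triad counts via networkx on each induced triple."""
    import networkx as nx

    G = nx.from_numpy_array(A, create_using=nx.DiGraph)
    census = nx.triadic_census(G)
    return {k: v for k, v in census.items() if k not in ("003", "012", "102")}


def sequential_marginals(weights: np.ndarray, k: int) -> np.ndarray:
    """Exact inclusion probability of each item under sequential
    weighted sampling without replacement (pick, zero, renormalize),
    by summing over every ordered pick sequence with Fractions."""
    n = len(weights)
    w = [Fraction(x).limit_denominator(10**9) for x in np.asarray(weights, dtype=float)]
    probs = [Fraction(0)] * n

    def rec(remaining: frozenset, pprefix: Fraction, picked: tuple):
        if len(picked) == k:
            for i in picked:
                probs[i] += pprefix
            return
        tot = sum((w[i] for i in remaining), Fraction(0))
        for i in remaining:
            if w[i] == 0:
                continue
            rec(remaining - {i}, pprefix * w[i] / tot, picked + (i,))

    rec(frozenset(range(n)), Fraction(1), ())
    return np.array([float(p) for p in probs])


def gaussian_filtered_overlap(t1: float, t2: float, sigma: float) -> float:
    """Closed-form normalized inner product of two unit spike trains
    convolved with a Gaussian kernel: exp(-(t1-t2)^2 / (4 sigma^2))."""
    return float(np.exp(-((t1 - t2) ** 2) / (4.0 * sigma**2)))


def kl_closed_form(p: np.ndarray, q: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
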