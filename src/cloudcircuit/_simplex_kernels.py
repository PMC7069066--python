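"""Bitset DFS kernels for directed-simplex enumeration.

The directed flag complex of a connectome-scale graph holds millions
of simplices, so enumeration runs as compiled (numba) iterative DFS
over uint64 bitset rows of the adjacency matrix.  A simplex (v0…vd) is
grown by intersecting the out-neighborhoods of its members; the
candidate set at depth k is ∩_{i<k} out(v_i), which doubles as the
prefix set needed for the maximality test (insertion of a vertex at
position p requires membership in prefix[p] ∩ suffix[p], with
suffix[p] = ∩_{j≥p} in(v_j)).
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAX_DEPTH = 48  # deepest simplex dimension supported (tuple length − 1)


def pack_bits(A: np.ndarray) -> np.ndarray:
    """Rows of a boolean matrix as uint64 bitsets (bit j of word w =
    column 64·w + j)."""
    n = A.shape[0]
    words = (n + 63) // 64
    out = np.zeros((n, words), dtype=np.uint64)
    i, j = np.nonzero(A)
    np.bitwise_or.at(out, (i, j >> 6), np.uint64(1) << (j & 63).astype(np.uint64))
    return out


@njit(cache=True)
def _next_bit(row, start, words, n):
    """Index of the first set bit ≥ start, or -1."""
    w = start >> 6
    if w >= words:
        return -1
    chunk = row[w] >> np.uint64(start & 63)
    if chunk != 0:
        return start + _ctz(chunk)
    w += 1
    while w < words:
        if row[w] != 0:
            return (w << 6) + _ctz(row[w])
        w += 1
    return -1


@njit(cache=True)
def _ctz(x):
    """Count trailing zeros of a nonzero uint64."""
    c = 0
    while x & np.uint64(1) == 0:
        x >>= np.uint64(1)
        c += 1
    return c


@njit(cache=True)
def _popcount(x):
    c = 0
    while x != 0:
        x &= x - np.uint64(1)
        c += 1
    return c


@njit(cache=True)
def count_kernel(out_bits, max_dim):
    """Per-dimension directed-simplex counts (index = dimension).

    At the depth cap the whole candidate set is counted by popcount
    instead of being iterated.
    """
    n, words = out_bits.shape
    counts = np.zeros(MAX_DEPTH + 1, dtype=np.int64)
    counts[0] = n
    cand = np.zeros((MAX_DEPTH + 2, words), dtype=np.uint64)
    pos = np.zeros(MAX_DEPTH + 2, dtype=np.int64)
    for v0 in range(n):
        depth = 1
        for w in range(words):
            cand[1, w] = out_bits[v0, w]
        pos[1] = 0
        while depth >= 1:
            if depth == max_dim:
                c = 0
                for w in range(words):
                    c += _popcount(cand[depth, w])
                counts[depth] += c
                depth -= 1
                continue
            b = _next_bit(cand[depth], pos[depth], words, n)
            if b < 0:
                depth -= 1
                continue
            pos[depth] = b + 1
            counts[depth] += 1
            empty = True
            for w in range(words):
                cand[depth + 1, w] = cand[depth, w] & out_bits[b, w]
                if cand[depth + 1, w] != 0:
                    empty = False
            if not empty:
                depth += 1
                pos[depth] = 0
    return counts


@njit(cache=True)
def maximal_kernel(out_bits, in_bits, max_dim, buf):
    """Enumerate simplices up to ``max_dim`` and record the maximal
    ones into ``buf`` (rows: dim, v0…vd, padded with −1).

    Returns (counts_per_dim_of_maximal, number_found); if the buffer
    overflows, the count keeps growing but rows beyond the buffer are
    dropped (caller re-runs with a larger buffer).
    """
    n, words = out_bits.shape
    cap = buf.shape[0]
    mcounts = np.zeros(MAX_DEPTH + 1, dtype=np.int64)
    found = 0
    cand = np.zeros((MAX_DEPTH + 2, words), dtype=np.uint64)
    memb = np.zeros((MAX_DEPTH + 2, words), dtype=np.uint64)
    pos = np.zeros(MAX_DEPTH + 2, dtype=np.int64)
    verts = np.zeros(MAX_DEPTH + 2, dtype=np.int64)
    suf = np.zeros((MAX_DEPTH + 3, words), dtype=np.uint64)
    for v0 in range(n):
        # isolated vertices are maximal 0-simplices
        deg = np.uint64(0)
        for w in range(words):
            deg |= out_bits[v0, w] | in_bits[v0, w]
        if deg == 0:
            mcounts[0] += 1
            if found < cap:
                buf[found, 0] = 0
                buf[found, 1] = v0
            found += 1
            continue
        verts[0] = v0
        depth = 1
        for w in range(words):
            cand[1, w] = out_bits[v0, w]
            memb[1, w] = np.uint64(0)
        memb[1, v0 >> 6] = np.uint64(1) << np.uint64(v0 & 63)
        pos[1] = 0
        while depth >= 1:
            b = _next_bit(cand[depth], pos[depth], words, n)
            if b < 0:
                depth -= 1
                continue
            pos[depth] = b + 1
            verts[depth] = b
            d = depth  # simplex dimension
            # --- maximality test for (verts[0..d]) ---
            # suffix sets of in-neighborhoods
            for w in range(words):
                suf[d + 1, w] = ~np.uint64(0)
            for p in range(d, -1, -1):
                vp = verts[p]
                for w in range(words):
                    suf[p, w] = suf[p + 1, w] & in_bits[vp, w]
            # prefix[0] = all ones, prefix[p] = cand[p] (p=1..d),
            # prefix[d+1] = cand[d] & out(b)
            nonmax = False
            for w in range(words):
                e = suf[0, w]  # prefix[0] & suffix[0]
                for p in range(1, d + 1):
                    e |= cand[p, w] & suf[p, w]
                e |= (cand[d, w] & out_bits[b, w]) & suf[d + 1, w]
                # exclude current members (incl. b)
                e &= ~(memb[d, w] | (np.uint64(1) << np.uint64(b & 63)
                                     if (b >> 6) == w else np.uint64(0)))
                if e != 0:
                    nonmax = True
                    break
            if not nonmax:
                mcounts[d] += 1
                if found < cap:
                    buf[found, 0] = d
                    for p in range(d + 1):
                        buf[found, p + 1] = verts[p]
                    for p in range(d + 1, buf.shape[1] - 1):
                        buf[found, p + 1] = -1
                found += 1
            # --- descend ---
            if depth < max_dim:
                empty = True
                for w in range(words):
                    cand[depth + 1, w] = cand[depth, w] & out_bits[b, w]
                    if cand[depth + 1, w] != 0:
                        empty = False
                if not empty:
                    for w in range(words):
                        memb[depth + 1, w] = memb[depth, w]
                    memb[depth + 1, b >> 6] |= np.uint64(1) << np.uint64(b & 63)
                    depth += 1
                    pos[depth] = 0
    return mcounts, found


@njit(cache=True)
def fixed_dim_kernel(out_bits, eid, N):
    """For every N-dimensional simplex accumulate (a) the sink count
    per vertex (higher-order in-degree) and (b) per-edge participation
    as the source (first) and sink (last) connection.

    ``eid`` maps (u, v) to the edge index (−1 where no edge).
    """
    n, words = out_bits.shape
    n_edges = 0
    for u in range(n):
        for v in range(n):
            if eid[u, v] >= 0:
                n_edges += 1
    sink = np.zeros(n, dtype=np.int64)
    n_source = np.zeros(n_edges, dtype=np.int64)
    n_sink = np.zeros(n_edges, dtype=np.int64)
    cand = np.zeros((MAX_DEPTH + 2, words), dtype=np.uint64)
    pos = np.zeros(MAX_DEPTH + 2, dtype=np.int64)
    verts = np.zeros(MAX_DEPTH + 2, dtype=np.int64)
    for v0 in range(n):
        verts[0] = v0
        depth = 1
        for w in range(words):
            cand[1, w] = out_bits[v0, w]
        pos[1] = 0
        while depth >= 1:
            b = _next_bit(cand[depth], pos[depth], words, n)
            if b < 0:
                depth -= 1
                continue
            pos[depth] = b + 1
            verts[depth] = b
            if depth == N:
                sink[b] += 1
                n_source[eid[verts[0], verts[1]]] += 1
                n_sink[eid[verts[N - 1], b]] += 1
                continue
            empty = True
            for w in range(words):
                cand[depth + 1, w] = cand[depth, w] & out_bits[b, w]
                if cand[depth + 1, w] != 0:
                    empty = False
            if not empty:
                depth += 1
                pos[depth] = 0
    return sink, n_source, n_sink
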