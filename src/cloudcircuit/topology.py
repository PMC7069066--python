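"""Directed-graph topology statistics.

Implements the structural measures used to separate first-order from
higher-order connectome structure: degree summaries and hub neurons,
the connected triad census, directed simplices of the flag complex
(all and maximal), higher-order in-degree, simplex participation of
connections with polarity, Euler characteristic, Betti numbers over
GF(2) for small graphs, characteristic path length, the Fagiolo
directed clustering coefficient, and matched Erdős–Rényi references.

A directed n-simplex of a graph G is an (n+1)-tuple (v0, …, vn) of
distinct vertices with an edge vi→vj for every i < j; v0 is the source
(innervates all members), vn the sink (innervated by all members).
Tuples with the same vertex set but different orders are distinct
simplices.  A simplex is maximal if it is not an ordered sub-tuple of
any higher-dimensional simplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DegreeSummary",
    "SimplexCensus",
    "ParticipationRecord",
    "SmallWorldStats",
    "PathLengthResult",
    "ClusteringResult",
    "ERReference",
    "as_adjacency",
    "degree_summary",
    "hub_set",
    "triad_census",
    "CONNECTED_TRIAD_CLASSES",
    "count_simplices",
    "count_maximal_simplices",
    "nd_in_degree",
    "connection_participation",
    "euler_characteristic",
    "betti_numbers",
    "characteristic_path_length",
    "clustering_coefficients",
    "small_world_stats",
    "er_reference",
]


# ---------------------------------------------------------------------------
# Input normalization
# ---------------------------------------------------------------------------

def as_adjacency(g) -> np.ndarray:
    """Boolean adjacency matrix (row = presynaptic) from a Connectome,
    a dense/sparse matrix, or a networkx DiGraph."""
    if hasattr(g, "adjacency") and hasattr(g, "edges") and hasattr(g, "neurons"):
        return g.adjacency()
    if isinstance(g, nx.DiGraph):
        nodes = sorted(g.nodes())
        A = np.zeros((len(nodes), len(nodes)), dtype=bool)
        pos = {u: i for i, u in enumerate(nodes)}
        for u, v in g.edges():
            A[pos[u], pos[v]] = True
        return A
    A = np.asarray(g.todense() if hasattr(g, "todense") else g)
    A = A.astype(bool)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if A.diagonal().any():
        raise ValueError("self-edges are not allowed")
    return A


# ---------------------------------------------------------------------------
# Degrees and hubs
# ---------------------------------------------------------------------------

@dataclass
class DegreeSummary:
    ids: np.ndarray
    in_degree: np.ndarray
    out_degree: np.ndarray
    sigma_in: float
    sigma_out: float
    in_out_correlation: float


def degree_summary(g, population: np.ndarray | None = None) -> DegreeSummary:
    """Degrees on the subgraph induced by ``population`` (node indices;
    default all).  σ is the population (ddof=0) standard deviation."""
    A = as_adjacency(g)
    ids = np.arange(A.shape[0]) if population is None else np.asarray(population)
    if ids.size == 0:
        raise ValueError("empty population")
    sub = A[np.ix_(ids, ids)]
    ind = sub.sum(axis=0).astype(np.int64)
    outd = sub.sum(axis=1).astype(np.int64)
    if ind.std() > 0 and outd.std() > 0:
        r = float(np.corrcoef(ind, outd)[0, 1])
    else:
        r = float("nan")
    return DegreeSummary(ids, ind, outd, float(ind.std()), float(outd.std()), r)


def hub_set(summary: DegreeSummary, fraction: float = 0.005) -> dict[str, np.ndarray]:
    """Top-``fraction`` neurons by in- and by out-degree (hub neurons).

    Returns ceil(fraction·n) ids per direction; ties at the cutoff are
    broken toward the lower neuron id.  Also reports the union and the
    intersection of the two hub lists.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n = len(summary.ids)
    k = int(np.ceil(fraction * n))

    def top(deg):
        # sort by (-degree, id): highest degree first, lowest id on ties
        order = np.lexsort((summary.ids, -deg))
        return np.sort(summary.ids[order[:k]])

    in_hubs, out_hubs = top(summary.in_degree), top(summary.out_degree)
    return {"in": in_hubs, "out": out_hubs,
            "union": np.union1d(in_hubs, out_hubs),
            "intersection": np.intersect1d(in_hubs, out_hubs)}


# ---------------------------------------------------------------------------
# Triad census
# ---------------------------------------------------------------------------

CONNECTED_TRIAD_CLASSES = ("021D", "021U", "021C", "111D", "111U", "030T",
                           "030C", "201", "120D", "120U", "120C", "210", "300")


def triad_census(g) -> dict[str, int]:
    """Counts of unordered neuron triples per connected 3-node motif
    class (13 classes, standard triad nomenclature)."""
    A = as_adjacency(g)
    G = nx.from_numpy_array(A, create_using=nx.DiGraph)
    census = nx.triadic_census(G)
    return {k: int(census[k]) for k in CONNECTED_TRIAD_CLASSES}


# ---------------------------------------------------------------------------
# Directed simplices
# ---------------------------------------------------------------------------

def _simplex_scan(A: np.ndarray, max_dim: int | None = None, on_simplex=None) -> list[int]:
    """Enumerate directed simplices by recursive extension of sorted
    out-neighborhood intersections.

    Returns per-dimension counts (counts[0] = vertices).  If given,
    ``on_simplex(tup)`` is called for every simplex of dim ≥ 1 with the
    current vertex list (do not retain the list reference).
    """
    n = A.shape[0]
    counts = [n]
    rows = A

    def rec(tup: list[int], cand: np.ndarray) -> None:
        idx = np.flatnonzero(cand)
        if idx.size == 0:
            return
        d = len(tup)  # dimension of the extended simplices
        while len(counts) <= d:
            counts.append(0)
        counts[d] += int(idx.size)
        descend = max_dim is None or d < max_dim
        if on_simplex is None and not descend:
            return
        for w in idx:
            tup.append(int(w))
            if on_simplex is not None:
                on_simplex(tup)
            if descend:
                rec(tup, cand & rows[w])
            tup.pop()

    for v in range(n):
        rec([v], rows[v].copy())
    return counts


def _trim(counts: list[int]) -> list[int]:
    while len(counts) > 1 and counts[-1] == 0:
        counts.pop()
    return counts


def count_simplices(g, max_dim: int | None = None) -> list[int]:
    """Number of directed simplices per dimension (index = dimension;
    [0] = vertices, [1] = edges).  Enumerates to exhaustion unless
    ``max_dim`` caps the recursion."""
    from . import _simplex_kernels as sk

    A = as_adjacency(g)
    n = A.shape[0]
    if n == 0:
        return [0]
    if max_dim is not None and max_dim == 0:
        return [n]
    cap = sk.MAX_DEPTH if max_dim is None else min(max_dim, sk.MAX_DEPTH)
    counts = [int(c) for c in sk.count_kernel(sk.pack_bits(A), cap)]
    if max_dim is not None:
        counts = counts[:max_dim + 1]
    return _trim(counts)


def _maximality_mask(A: np.ndarray, AT: np.ndarray, tup: list[int]) -> bool:
    """True iff the simplex ``tup`` cannot be extended by inserting any
    vertex at any position (i.e. it is maximal)."""
    n = A.shape[0]
    d1 = len(tup)
    # prefix[p] = vertices receiving an edge from v_0..v_{p-1}
    pref = np.ones(n, dtype=bool)
    suf = [None] * (d1 + 1)
    s = np.ones(n, dtype=bool)
    suf[d1] = s
    for p in range(d1 - 1, -1, -1):
        s = s & AT[tup[p]]
        suf[p] = s
    ext = pref & suf[0]
    for p in range(1, d1 + 1):
        pref = pref & A[tup[p - 1]]
        ext = ext | (pref & suf[p])
    ext[tup] = False
    return not ext.any()


@dataclass
class SimplexCensus:
    """Per-dimension simplex counts with optional maximal-simplex
    counts/lists and Betti numbers."""

    counts: list[int]
    maximal_counts: list[int] | None = None
    maximal: list[tuple[int, ...]] | None = None
    betti: list[int] | None = None
    max_dim: int | None = None

    @property
    def euler_characteristic(self) -> int:
        return euler_characteristic(self.counts, capped=self.max_dim is not None)


def count_maximal_simplices(g, max_dim: int | None = None
                            ) -> tuple[list[int], list[tuple[int, ...]]]:
    """Per-dimension counts and the list of maximal directed simplices.

    A 0-simplex (vertex) is maximal iff it is isolated.  Maximality is
    decided against the full graph (extension by inserting a vertex at
    any position), so capping ``max_dim`` restricts only which
    simplices are examined, not the test itself.
    """
    from . import _simplex_kernels as sk

    A = as_adjacency(g)
    n = A.shape[0]
    if n == 0:
        return [0], []
    cap_dim = sk.MAX_DEPTH if max_dim is None else min(max_dim, sk.MAX_DEPTH)
    out_bits = sk.pack_bits(A)
    in_bits = sk.pack_bits(A.T)
    cap = max(1024, 2 * n + int(A.sum()))
    while True:
        buf = np.full((cap, cap_dim + 2), -1, dtype=np.int64)
        mcounts, n_found = sk.maximal_kernel(out_bits, in_bits, cap_dim, buf)
        if n_found <= cap:
            break
        cap = int(n_found)
    found = [tuple(int(v) for v in row[1:int(row[0]) + 2])
             for row in buf[:n_found]]
    counts = _trim([int(c) for c in mcounts])
    return counts, found


def simplex_census(g, max_dim: int | None = None, maximal: bool = False,
                   betti: bool = False) -> SimplexCensus:
    """One-stop census: simplex counts, optionally maximal simplices
    and Betti numbers (small graphs only)."""
    counts = count_simplices(g, max_dim=max_dim)
    capped = max_dim is not None and len(counts) > max_dim and counts[max_dim] > 0
    census = SimplexCensus(counts, max_dim=max_dim if capped else None)
    if maximal:
        census.maximal_counts, census.maximal = count_maximal_simplices(g, max_dim=max_dim)
    if betti:
        census.betti = betti_numbers(g)
    return census


def nd_in_degree(g, N: int, neuron: int | None = None):
    """Number of N-dimensional simplices each neuron is the sink of.
    For N = 1 this is the ordinary in-degree.  Returns the full vector,
    or a single count if ``neuron`` is given."""
    if N < 1:
        raise ValueError("N must be >= 1")
    A = as_adjacency(g)
    sink, _, _ = _fixed_dim_stats(A, N)
    return sink if neuron is None else int(sink[neuron])


def _fixed_dim_stats(A: np.ndarray, N: int):
    from . import _simplex_kernels as sk

    n = A.shape[0]
    if n == 0:
        return (np.zeros(0, dtype=np.int64),) * 3
    eid = np.full((n, n), -1, dtype=np.int64)
    edges = np.argwhere(A)
    eid[edges[:, 0], edges[:, 1]] = np.arange(len(edges))
    return sk.fixed_dim_kernel(sk.pack_bits(A), eid, N)


@dataclass
class ParticipationRecord:
    """Per-connection participation in N-dimensional simplices.

    ``n_source[e]`` counts simplices where edge e is the first
    connection (neurons 0→1), ``n_sink[e]`` where it is the last
    (neurons N−1→N).  Polarity = (n_source − n_sink)/(n_source +
    n_sink), NaN where the edge is in no simplex (those edges are
    excluded from the mean).
    """

    edges: np.ndarray          # (m, 2) pre, post
    n_source: np.ndarray
    n_sink: np.ndarray
    dimension: int

    @property
    def defined(self) -> np.ndarray:
        return (self.n_source + self.n_sink) > 0

    @property
    def polarity(self) -> np.ndarray:
        tot = self.n_source + self.n_sink
        out = np.full(len(self.edges), np.nan)
        d = self.defined
        out[d] = (self.n_source[d] - self.n_sink[d]) / tot[d]
        return out

    @property
    def mean_abs_polarity(self) -> float:
        p = self.polarity
        return float(np.nanmean(np.abs(p))) if self.defined.any() else float("nan")


def connection_participation(g, N: int) -> ParticipationRecord:
    """Source/sink participation of every connection in N-dimensional
    simplices (N ≥ 2)."""
    if N < 2:
        raise ValueError("N must be >= 2")
    A = as_adjacency(g)
    edges = np.argwhere(A)
    _, n_source, n_sink = _fixed_dim_stats(A, N)
    return ParticipationRecord(edges, n_source, n_sink, N)


# ---------------------------------------------------------------------------
# Euler characteristic and Betti numbers
# ---------------------------------------------------------------------------

def euler_characteristic(counts: list[int], capped: bool = False) -> int:
    """χ = Σ_k (−1)^k · (number of k-simplices)."""
    if capped and counts and counts[-1] > 0:
        warnings.warn("simplex counts truncated at max_dim; Euler characteristic "
                      "is incomplete", stacklevel=2)
    return int(sum((-1) ** k * c for k, c in enumerate(counts)))


def _gf2_rank(columns: list[int]) -> int:
    """Rank over GF(2) of a matrix given as column bitmasks."""
    pivots: dict[int, int] = {}
    rank = 0
    for col in columns:
        while col:
            h = col.bit_length() - 1
            if h in pivots:
                col ^= pivots[h]
            else:
                pivots[h] = col
                rank += 1
                break
    return rank


def betti_numbers(g, guard: int = 64) -> list[int]:
    """Betti numbers of the directed flag complex over GF(2), from
    boundary-matrix ranks.  Counts the cavities the simplices enclose
    in each dimension.  Guarded to small graphs (simplicial homology at
    connectome scale needs specialized software)."""
    A = as_adjacency(g)
    n = A.shape[0]
    if n > guard:
        raise ValueError(f"betti_numbers limited to {guard} nodes, got {n}")
    by_dim: dict[int, list[tuple[int, ...]]] = {0: [(v,) for v in range(n)]}

    def hook(tup: list[int]) -> None:
        by_dim.setdefault(len(tup) - 1, []).append(tuple(tup))

    _simplex_scan(A, on_simplex=hook)
    top = max(by_dim)
    index = {d: {s: i for i, s in enumerate(by_dim[d])} for d in by_dim}
    ranks = {0: 0}
    for d in range(1, top + 1):
        cols = []
        faces = index[d - 1]
        for s in by_dim[d]:
            mask = 0
            for i in range(d + 1):
                mask ^= 1 << faces[s[:i] + s[i + 1:]]
            cols.append(mask)
        ranks[d] = _gf2_rank(cols)
    ranks[top + 1] = 0
    betti = [len(by_dim[d]) - ranks[d] - ranks[d + 1] for d in range(top + 1)]
    while len(betti) > 1 and betti[-1] == 0:
        betti.pop()
    return betti


# ---------------------------------------------------------------------------
# Small-world statistics
# ---------------------------------------------------------------------------

@dataclass
class PathLengthResult:
    l: float
    n_pairs: int
    exact: bool
    stderr: float = 0.0


def characteristic_path_length(g, exact_limit: int = 4000,
                               sample_size: int = 256, seed: int = 0) -> PathLengthResult:
    """Mean shortest directed path length over all ordered pairs of
    mutually reachable neurons.

    Exact (all-pairs BFS) up to ``exact_limit`` nodes; beyond that, a
    seeded sample of source nodes gives an estimate with a standard
    error over sources.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import shortest_path

    A = as_adjacency(g)
    n = A.shape[0]
    S = csr_matrix(A)
    if n <= exact_limit:
        D = shortest_path(S, method="D", unweighted=True, directed=True)
        mutual = np.isfinite(D) & np.isfinite(D.T)
        np.fill_diagonal(mutual, False)
        if not mutual.any():
            raise ValueError("no mutually reachable pairs")
        return PathLengthResult(float(D[mutual].mean()), int(mutual.sum()), True)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6C70]))
    sources = rng.choice(n, size=min(sample_size, n), replace=False)
    Df = shortest_path(S, method="D", unweighted=True, directed=True, indices=sources)
    Db = shortest_path(S.T, method="D", unweighted=True, directed=True, indices=sources)
    per_source = []
    for i in range(len(sources)):
        mutual = np.isfinite(Df[i]) & np.isfinite(Db[i])
        mutual[sources[i]] = False
        if mutual.any():
            per_source.append(Df[i][mutual].mean())
    if not per_source:
        raise ValueError("no mutually reachable pairs in sample")
    per_source = np.array(per_source)
    se = float(per_source.std(ddof=1) / np.sqrt(len(per_source))) if len(per_source) > 1 else 0.0
    return PathLengthResult(float(per_source.mean()), len(per_source), False, se)


@dataclass
class ClusteringResult:
    c_i: np.ndarray
    c: float


def clustering_coefficients(g) -> ClusteringResult:
    """Directed clustering coefficient (Fagiolo):

        c_i = ((M + Mᵀ)³)_ii / (2·(d_tot(d_tot − 1) − 2·(M²)_ii))

    i.e. the fraction of realized triangles among node i and its
    neighbors, counting edge directions.  Nodes with a zero denominator
    (d_tot ≤ 1, or only reciprocal partners) get c_i = 0.
    """
    from scipy.sparse import csr_matrix

    A = as_adjacency(g)
    if A.shape[0] == 0:
        raise ValueError("empty graph")
    M = csr_matrix(A.astype(np.float64))
    B = M + M.T
    B2 = B @ B
    tri = np.asarray((B2 @ B).diagonal())
    d_tot = np.asarray(M.sum(axis=0)).ravel() + np.asarray(M.sum(axis=1)).ravel()
    recip = np.asarray((M @ M).diagonal())
    denom = 2.0 * (d_tot * (d_tot - 1) - 2.0 * recip)
    c_i = np.zeros(A.shape[0])
    ok = denom > 0
    c_i[ok] = tri[ok] / denom[ok]
    return ClusteringResult(c_i, float(c_i.mean()))


@dataclass
class SmallWorldStats:
    l: float
    c_i: np.ndarray
    c: float
    ratio: float                    # c / l, the small-worldness index
    l_er: float | None = None
    c_er: float | None = None
    sigma_er: float | None = None


def small_world_stats(g, seed: int = 0, er: bool = True,
                      exact_limit: int = 4000) -> SmallWorldStats:
    """Characteristic path length, clustering, and the small-worldness
    ratio c/l, with a size- and sparseness-matched ER reference."""
    A = as_adjacency(g)
    lres = characteristic_path_length(A, exact_limit=exact_limit, seed=seed)
    cres = clustering_coefficients(A)
    stats = SmallWorldStats(lres.l, cres.c_i, cres.c, cres.c / lres.l)
    if er:
        n, m = A.shape[0], int(A.sum())
        ref = er_reference(n, m, seed)
        stats.sigma_er = ref.sigma_closed_form
        try:
            stats.l_er = characteristic_path_length(
                ref.adjacency, exact_limit=exact_limit, seed=seed).l
        except ValueError:
            stats.l_er = float("nan")
        stats.c_er = clustering_coefficients(ref.adjacency).c
    return stats


# ---------------------------------------------------------------------------
# Erdős–Rényi reference
# ---------------------------------------------------------------------------

@dataclass
class ERReference:
    adjacency: np.ndarray
    n: int
    m: int
    p: float
    sigma_closed_form: float  # √((n−1)·p·(1−p)), the binomial degree σ


def er_reference(n: int, m: int, seed: int) -> ERReference:
    """Directed G(n, m) graph without self-edges, plus the closed-form
    degree standard deviation of the matching binomial model."""
    if not (0 <= m <= n * (n - 1)):
        raise ValueError("edge count out of range")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6572]))
    chosen = rng.choice(n * (n - 1), size=m, replace=False)
    pre, rem = np.divmod(chosen, n - 1)
    post = rem + (rem >= pre)  # skip the diagonal
    A = np.zeros((n, n), dtype=bool)
    A[pre, post] = True
    p = m / (n * (n - 1)) if n > 1 else 0.0
    return ERReference(A, n, m, p, float(np.sqrt((n - 1) * p * (1 - p))))
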