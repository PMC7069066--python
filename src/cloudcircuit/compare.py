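"""First-order structure validation.

Metrics showing that a rewired (cloud) connectome preserves the
reference's pairwise statistics: soma-distance distributions of
afferent/efferent connections with Kullback–Leibler divergence,
reciprocal-connection overexpression, the macroconnectome (per-type-pair
count matrix), and the common-neighbor bias curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import as_adjacency
from .wiring import Connectome

__all__ = [
    "DistanceDistribution",
    "connection_distance_distribution",
    "kl_divergence",
    "reciprocal_overexpression",
    "macroconnectome",
    "macroconnectome_diff",
    "common_neighbor_bias",
]


@dataclass
class DistanceDistribution:
    """Normalized histogram of soma-to-soma distances of connections."""

    direction: str            # "afferent" | "efferent"
    group: str
    bin_width: float
    masses: np.ndarray        # sums to 1
    n_edges: int

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")

    @property
    def edges(self) -> np.ndarray:
        return np.arange(len(self.masses) + 1) * self.bin_width


def connection_distance_distribution(connectome: Connectome, direction: str,
                                     group_key: str, group: str,
                                     bin_width: float = 20.0,
                                     max_distance: float | None = None) -> DistanceDistribution:
    """Distance histogram of edges whose post- (afferent) or pre-
    (efferent) neuron belongs to ``group`` (a layer or m-type).

    The histogram is normalized to unit mass; ``max_distance`` fixes
    the binning range so distributions of different connectomes share
    bins (default: cover the observed maximum).
    """
    if direction not in ("afferent", "efferent"):
        raise ValueError("direction must be 'afferent' or 'efferent'")
    neurons = connectome.neurons.set_index("neuron_id")
    members = set(neurons.index[neurons[group_key] == group])
    if not members:
        raise ValueError(f"empty group {group!r}")
    e = connectome.edges
    anchor = e["post_id"] if direction == "afferent" else e["pre_id"]
    sel = e[anchor.isin(members)]
    if len(sel) == 0:
        raise ValueError(f"no {direction} edges for group {group!r}")
    xyz = neurons[["x_um", "y_um", "z_um"]]
    d = np.linalg.norm(xyz.loc[sel["pre_id"]].to_numpy()
                       - xyz.loc[sel["post_id"]].to_numpy(), axis=1)
    hi = max_distance if max_distance is not None else d.max() + bin_width
    nbins = max(1, int(np.ceil(hi / bin_width)))
    counts, _ = np.histogram(d, bins=nbins, range=(0.0, nbins * bin_width))
    return DistanceDistribution(direction, group, bin_width,
                                counts / counts.sum(), len(sel))


def kl_divergence(P, Q, eps: float = 1e-9) -> float:
    """D(P‖Q) in nats.  Both histograms receive an ``eps`` pseudocount
    per bin and are renormalized, so empty bins are defined.  Accepts
    arrays or DistanceDistribution objects on the same binning."""
    if isinstance(P, DistanceDistribution) and isinstance(Q, DistanceDistribution):
        if abs(P.bin_width - Q.bin_width) > 1e-12 or len(P.masses) != len(Q.masses):
            raise ValueError("distributions use different binning")
        P, Q = P.masses, Q.masses
    p = np.asarray(P, dtype=float) + eps
    q = np.asarray(Q, dtype=float) + eps
    if p.shape != q.shape:
        raise ValueError("distributions use different binning")
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def reciprocal_overexpression(connectome_or_adj, group: np.ndarray | None = None,
                              per_pair: bool = False) -> float:
    """Reciprocal connection probability divided by the squared
    unidirectional connection probability, within a node group.

    Ratio 1 means reciprocal pairs occur exactly as often as expected
    from independent directed edges; cortical circuits overexpress
    them.  ``per_pair=True`` uses the Σ p_AB·p_BA estimator instead of
    the pooled p_uni² (identical for homogeneous groups).
    """
    A = as_adjacency(connectome_or_adj)
    if group is not None:
        A = A[np.ix_(group, group)]
    n = A.shape[0]
    if n < 2:
        raise ValueError("group must contain at least 2 neurons")
    m = int(A.sum())
    if m == 0:
        raise ValueError("no connections in group: p_uni = 0")
    p_uni = m / (n * (n - 1))
    rec_pairs = int((A & A.T).sum()) // 2
    p_rec = rec_pairs / (n * (n - 1) / 2)
    if per_pair:
        # expected reciprocal probability under independent directions
        expected = p_uni ** 2  # pooled estimate of mean p_AB * p_BA
        return p_rec / expected
    return p_rec / p_uni ** 2


def macroconnectome(connectome: Connectome) -> pd.DataFrame:
    """Per ordered (pre m-type, post m-type) connection-count matrix."""
    pc = connectome.pair_counts()
    mtypes = sorted(connectome.neurons["m_type"].unique())
    mat = pc.pivot(index="pre_mtype", columns="post_mtype", values="count")
    return mat.reindex(index=mtypes, columns=mtypes, fill_value=0).fillna(0).astype(int)


def macroconnectome_diff(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Elementwise difference of two macroconnectome matrices."""
    idx = a.index.union(b.index)
    col = a.columns.union(b.columns)
    return (a.reindex(index=idx, columns=col, fill_value=0)
            - b.reindex(index=idx, columns=col, fill_value=0))


def common_neighbor_bias(connectome_or_adj, sample_size: int = 100_000,
                         seed: int = 0, min_pairs: int = 10
                         ) -> pd.DataFrame:
    """Normalized connection probability versus common-neighbor count.

    A common neighbor of (A, B) is a third node adjacent (in either
    direction) to both.  Over a seeded sample of unordered node pairs,
    reports P(connected | k common neighbors) / P(connected) per k;
    bins with fewer than ``min_pairs`` sampled pairs are omitted (their
    ks are returned with NaN ratio and flagged).

    Returns a DataFrame (k, n_pairs, p_connected, ratio, populated).
    """
    A = as_adjacency(connectome_or_adj)
    n = A.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x636E]))
    n_pairs_total = n * (n - 1) // 2
    size = min(sample_size, n_pairs_total)
    # sample unordered pairs uniformly (with replacement across draws is
    # acceptable for a ratio curve; draw indices then map to (i, j))
    i = rng.integers(0, n, size=size)
    j = rng.integers(0, n - 1, size=size)
    j = j + (j >= i)
    und = A | A.T
    undf = und.astype(np.float32)
    # common-neighbor count for sampled pairs
    k = np.einsum("ij,ij->i", undf[i], undf[j]).astype(np.int64)
    connected = und[i, j]
    p_conn = connected.mean()
    rows = []
    for kk in np.unique(k):
        mask = k == kk
        cnt = int(mask.sum())
        populated = cnt >= min_pairs
        pk = float(connected[mask].mean()) if populated else np.nan
        rows.append((int(kk), cnt, pk,
                     pk / p_conn if populated and p_conn > 0 else np.nan, populated))
        if not populated:
            warnings.warn(f"common-neighbor bin k={kk} has only {cnt} sampled pairs; "
                          "omitted", stacklevel=2)
    return pd.DataFrame(rows, columns=["k", "n_pairs", "p_connected", "ratio", "populated"])
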