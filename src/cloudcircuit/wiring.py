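"""Cloud-based connectome construction and rewiring controls.

The cloud wiring replaces instance-level axo-dendritic overlap with
type-averaged density clouds: for each ordered m-type pair the axon and
dendrite clouds are convolved into an overlap field, field values are
looked up at every soma-pair offset to form an overlap matrix O, a
transfer function Õ = O² is applied, the block is normalized to
probabilities, and exactly as many edges as in the reference connectome
are drawn without replacement by the sequential pick-zero-renormalize
procedure.  This conserves the macroconnectome (per-type-pair counts)
and distance-dependent connectivity while discarding structure carried
by within-type morphological diversity.

Also implemented: the transplant of a cloud wiring into an existing
connectome with duplication/loss accounting (rewiring constrained to
the same presynaptic m-type, excitatory connections only), the matched
removal control that deletes exactly the lost connections per type
pair, and the path-length shuffle control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import (CircuitSpec, DensityGrid, MorphologySet, _lookup_field,
                      _pair_offsets, render_density)

__all__ = [
    "OverlapField",
    "BlockProbabilities",
    "Connectome",
    "LossReport",
    "mean_type_density",
    "convolve_clouds",
    "lookup_pair_overlaps",
    "transfer_and_normalize",
    "sample_without_replacement",
    "sequential_sample_without_replacement",
    "build_cloud_connectome",
    "transplant",
    "matched_removal",
    "shuffle_path_length",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class OverlapField:
    """Expected axon-dendrite overlap as a function of the relative
    pre-to-post soma offset (lateral, depth), on the density-grid bin."""

    values: np.ndarray
    bin: float
    lat0: float
    depth0: float
    pre_mtype: str = ""
    post_mtype: str = ""

    @property
    def mass(self) -> float:
        return float(self.values.sum())

    def at(self, lateral: float, depth: float) -> float:
        """Nearest-bin field value at one offset (out of range -> 0)."""
        return float(_lookup_field(self.values, self.bin, self.lat0, self.depth0,
                                   np.array([lateral]), np.array([depth]))[0])


@dataclass
class BlockProbabilities:
    """Overlap matrix O, transferred matrix Õ = O^exponent, and the
    normalized selection probabilities P of one m-type-pair block."""

    O: np.ndarray
    O_transferred: np.ndarray
    P: np.ndarray
    empty: bool
    exponent: float = 2.0


@dataclass
class Connectome:
    """Directed connectome: edge table plus its neuron table.

    ``edges`` columns: pre_id, post_id and optionally synapse_count,
    path_length_um.  At most one edge per ordered pair, no self-edges.
    """

    edges: pd.DataFrame
    neurons: pd.DataFrame

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) and (e["pre_id"] == e["post_id"]).any():
            raise ValueError("self-edges are not allowed")
        if len(e) and e.duplicated(["pre_id", "post_id"]).any():
            raise ValueError("duplicate ordered pairs in edge list")

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def with_edges(self, edges: pd.DataFrame) -> "Connectome":
        return Connectome(edges.reset_index(drop=True), self.neurons)

    def mtypes_of_edges(self) -> pd.DataFrame:
        """Edge table annotated with pre/post m-type and synapse class."""
        ninfo = self.neurons.set_index("neuron_id")[["m_type", "synapse_class"]]
        out = self.edges.copy()
        out["pre_mtype"] = ninfo["m_type"].loc[out["pre_id"]].to_numpy()
        out["post_mtype"] = ninfo["m_type"].loc[out["post_id"]].to_numpy()
        out["pre_class"] = ninfo["synapse_class"].loc[out["pre_id"]].to_numpy()
        return out

    def pair_counts(self) -> pd.DataFrame:
        """Macroconnectome: edge counts per ordered (pre, post) m-type pair."""
        ann = self.mtypes_of_edges()
        return (ann.groupby(["pre_mtype", "post_mtype"], sort=True)
                .size().rename("count").reset_index())

    def pair_count_dict(self) -> dict[tuple[str, str], int]:
        pc = self.pair_counts()
        return {(r.pre_mtype, r.post_mtype): int(r.count) for r in pc.itertuples()}

    def adjacency(self) -> np.ndarray:
        """Dense boolean adjacency (row = presynaptic neuron)."""
        n = self.n_neurons
        A = np.zeros((n, n), dtype=bool)
        A[self.edges["pre_id"].to_numpy(), self.edges["post_id"].to_numpy()] = True
        return A


@dataclass
class LossReport:
    """Bookkeeping of the transplant: per ordered m-type pair, how many
    connections the cloud wiring required, how many were placed, how
    many slots were duplicated, and how many were lost (no slot)."""

    table: pd.DataFrame  # pre_mtype, post_mtype, required, placed, duplicated, lost

    def __post_init__(self) -> None:
        t = self.table
        if len(t) and not (t["required"] == t["placed"] + t["lost"]).all():
            raise ValueError("loss report violates required = placed + lost")

    @property
    def excitatory_loss_fraction(self) -> float:
        req = self.table["required"].sum()
        return float(self.table["lost"].sum() / req) if req else 0.0

    def lost_dict(self) -> dict[tuple[str, str], int]:
        return {(r.pre_mtype, r.post_mtype): int(r.lost)
                for r in self.table.itertuples() if r.lost > 0}


# ---------------------------------------------------------------------------
# Cloud fields
# ---------------------------------------------------------------------------

def mean_type_density(grids: list[DensityGrid]) -> DensityGrid:
    """Elementwise arithmetic mean of same-shape density grids."""
    if not grids:
        raise ValueError("no density instances to average")
    g0 = grids[0]
    for g in grids[1:]:
        if g.values.shape != g0.values.shape or abs(g.bin - g0.bin) > 1e-12 \
                or abs(g.lat0 - g0.lat0) > 1e-9 or abs(g.depth0 - g0.depth0) > 1e-9:
            raise ValueError("instance grids must share shape, bin, and origin")
    mean = np.mean([g.values for g in grids], axis=0)
    return DensityGrid(mean, g0.bin, g0.lat0, g0.depth0,
                       m_type=g0.m_type, component=g0.component)


def convolve_clouds(dendrite: DensityGrid, axon: DensityGrid,
                    pre_mtype: str = "", post_mtype: str = "") -> OverlapField:
    """Overlap field F(Δ) = Σ_u dendrite(u) · axon(u − Δ) where Δ is the
    pre-to-post soma offset.  Total field mass = dendrite mass × axon
    mass (Fubini)."""
    from scipy.signal import fftconvolve

    if abs(dendrite.bin - axon.bin) > 1e-12:
        raise ValueError("mismatched bin sizes")
    # correlation of D with A: flip A and convolve
    vals = fftconvolve(dendrite.values, axon.values[::-1, ::-1], mode="full")
    vals = np.maximum(vals, 0.0)  # clip FFT round-off
    na_l, na_d = axon.values.shape
    lat0 = dendrite.lat0 - axon.lat0 - axon.bin * (na_l - 1)
    depth0 = dendrite.depth0 - axon.depth0 - axon.bin * (na_d - 1)
    return OverlapField(vals, dendrite.bin, lat0, depth0,
                        pre_mtype=pre_mtype or axon.m_type,
                        post_mtype=post_mtype or dendrite.m_type)


def lookup_pair_overlaps(neurons: pd.DataFrame, field: OverlapField,
                         pre_mtype: str, post_mtype: str) -> np.ndarray:
    """Overlap matrix O for all (pre, post) neuron pairs of one m-type
    combination, by nearest-bin lookup of the field at each soma-pair
    (lateral distance, depth difference) offset.

    The diagonal is zeroed for same-type blocks (no self-edges).
    Out-of-range offsets read as 0 (with a warning if any occur).
    """
    for m in (pre_mtype, post_mtype):
        if not (neurons["m_type"] == m).any():
            raise KeyError(f"unknown m-type {m!r}")
    xyz = neurons[["x_um", "y_um", "z_um"]].to_numpy()
    pre_idx = np.flatnonzero((neurons["m_type"] == pre_mtype).to_numpy())
    post_idx = np.flatnonzero((neurons["m_type"] == post_mtype).to_numpy())
    r, dy = _pair_offsets(xyz[pre_idx], xyz[post_idx])
    il = np.rint((r - field.lat0) / field.bin)
    jd = np.rint((dy - field.depth0) / field.bin)
    nl, nd = field.values.shape
    oob = (il < 0) | (il >= nl) | (jd < 0) | (jd >= nd)
    if oob.any():
        warnings.warn(f"{int(oob.sum())} pair offsets outside the overlap field; "
                      "treated as zero overlap", stacklevel=2)
    O = _lookup_field(field.values, field.bin, field.lat0, field.depth0, r, dy)
    if pre_mtype == post_mtype:
        np.fill_diagonal(O, 0.0)
    return O


def transfer_and_normalize(O: np.ndarray, exponent: float = 2.0) -> BlockProbabilities:
    """Apply the transfer function Õ = O^exponent (default: squared
    overlap) and normalize to selection probabilities."""
    O = np.asarray(O, dtype=float)
    if np.any(O < 0):
        raise ValueError("overlap matrix has negative entries")
    Ot = O ** exponent
    total = Ot.sum()
    if total <= 0:
        return BlockProbabilities(O, Ot, np.zeros_like(Ot), empty=True, exponent=exponent)
    return BlockProbabilities(O, Ot, Ot / total, empty=False, exponent=exponent)


# ---------------------------------------------------------------------------
# Weighted sampling without replacement
# ---------------------------------------------------------------------------

def sample_without_replacement(weights: np.ndarray, n_target: int, seed: int) -> np.ndarray:
    """Draw ``n_target`` distinct indices with probability proportional
    to ``weights``, without replacement, equal in distribution to the
    sequential procedure: pick one index ∝ weight, zero it, renormalize,
    repeat.

    Implemented with the exponential-race (Gumbel top-k) equivalence:
    indices ranked by log(w) + Gumbel noise reproduce the sequential
    pick order exactly in distribution.  Deterministic given ``seed``.
    """
    w = np.asarray(weights, dtype=float).ravel()
    if n_target == 0:
        return np.array([], dtype=np.int64)
    nz = np.flatnonzero(w > 0)
    if n_target > len(nz):
        raise ValueError(
            f"infeasible sample: {n_target} requested but only {len(nz)} "
            "entries have positive weight")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x73616D]))
    gumbel = -np.log(-np.log(rng.random(len(nz))))
    keys = np.log(w[nz]) + gumbel
    top = np.argpartition(-keys, n_target - 1)[:n_target]
    return np.sort(nz[top])


def sequential_sample_without_replacement(weights: np.ndarray, n_target: int,
                                          seed: int) -> np.ndarray:
    """Literal sequential pick-zero-renormalize loop (reference
    implementation; O(n·k), used for validation)."""
    w = np.asarray(weights, dtype=float).ravel().copy()
    if n_target > int(np.count_nonzero(w > 0)):
        raise ValueError("infeasible sample")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x73716C]))
    picked = []
    for _ in range(n_target):
        p = w / w.sum()
        k = rng.choice(len(w), p=p)
        picked.append(k)
        w[k] = 0.0
    return np.sort(np.array(picked, dtype=np.int64))


# ---------------------------------------------------------------------------
# Block-wise wiring engine
# ---------------------------------------------------------------------------

def _type_fields(spec: CircuitSpec) -> dict[tuple[str, str], OverlapField]:
    """Type-level overlap fields for all ordered m-type pairs."""
    grids = {m.name: (render_density(m.axon, spec.grid_bin, m_type=m.name, component="axon"),
                      render_density(m.dendrite, spec.grid_bin, m_type=m.name, component="dendrite"))
             for m in spec.mtypes}
    return {(mi, mj): convolve_clouds(grids[mj][1], grids[mi][0], pre_mtype=mi, post_mtype=mj)
            for mi in spec.mtype_names for mj in spec.mtype_names}


def _wire_blocks(neurons: pd.DataFrame, spec: CircuitSpec,
                 targets: dict[tuple[str, str], int], seed: int, salt: int,
                 displacement: np.ndarray | None = None,
                 scale: np.ndarray | None = None,
                 exponent: float = 2.0,
                 fields: dict[tuple[str, str], OverlapField] | None = None) -> pd.DataFrame:
    """Sample edges block by block with selection ∝ overlap^exponent.

    With ``displacement``/``scale`` given, overlaps are instance-level:
    s_pre · s_post · F(Δsoma + δ_pre − δ_post); otherwise type-level
    (cloud wiring).  Per-block counts equal ``targets`` exactly.
    """
    if fields is None:
        fields = _type_fields(spec)
    xyz = neurons[["x_um", "y_um", "z_um"]].to_numpy()
    if displacement is not None:
        xyz = xyz + displacement
    ids = neurons["neuron_id"].to_numpy()
    by_type = {m: np.flatnonzero((neurons["m_type"] == m).to_numpy())
               for m in spec.mtype_names}
    names = spec.mtype_names
    block_seeds = np.random.SeedSequence([int(seed), salt]).generate_state(
        len(names) ** 2, dtype=np.uint32)
    pre_list, post_list = [], []
    bidx = -1
    for mi in names:
        for mj in names:
            bidx += 1
            n_target = int(targets.get((mi, mj), 0))
            if n_target == 0:
                continue
            F = fields[(mi, mj)]
            pre_idx, post_idx = by_type[mi], by_type[mj]
            r, dy = _pair_offsets(xyz[pre_idx], xyz[post_idx])
            O = _lookup_field(F.values, F.bin, F.lat0, F.depth0, r, dy)
            if scale is not None:
                O = O * (scale[pre_idx][:, None] * scale[post_idx][None, :])
            if mi == mj:
                np.fill_diagonal(O, 0.0)
            block = transfer_and_normalize(O, exponent)
            if block.empty or n_target > int(np.count_nonzero(block.P)):
                raise ValueError(
                    f"infeasible target for block {mi}->{mj}: {n_target} edges "
                    f"requested, {int(np.count_nonzero(block.P))} possible")
            flat = sample_without_replacement(block.P.ravel(), n_target,
                                             int(block_seeds[bidx]))
            ii, jj = np.unravel_index(flat, block.P.shape)
            pre_list.append(ids[pre_idx[ii]])
            post_list.append(ids[post_idx[jj]])
    if pre_list:
        edges = pd.DataFrame({"pre_id": np.concatenate(pre_list),
                              "post_id": np.concatenate(post_list)})
    else:
        edges = pd.DataFrame({"pre_id": np.array([], dtype=np.int64),
                              "post_id": np.array([], dtype=np.int64)})
    return edges.sort_values(["pre_id", "post_id"], ignore_index=True)


def build_cloud_connectome(reference: Connectome, spec: CircuitSpec, seed: int,
                           exponent: float = 2.0) -> Connectome:
    """Wire the cloud connectome: same per-m-type-pair connection counts
    as the reference, selection probabilities from type-averaged clouds
    (overlap field lookup at soma offsets, Õ = O^exponent, sequential
    sampling without replacement), assembled over all m-type blocks."""
    targets = reference.pair_count_dict()
    edges = _wire_blocks(reference.neurons, spec, targets, seed, salt=0x636C)
    return Connectome(edges, reference.neurons)


# ---------------------------------------------------------------------------
# Transplant, matched removal, path-length shuffle
# ---------------------------------------------------------------------------

def transplant(cloud: Connectome, reference: Connectome, seed: int
               ) -> tuple[Connectome, LossReport]:
    """Implement the cloud wiring inside the reference circuit, reusing
    the reference's synapses.

    For every (postsynaptic neuron, presynaptic m-type) group, the
    reference's afferent connections act as slots carrying their
    (synapse_count, path_length) attributes; the cloud wiring's new
    presynaptic sources are assigned to slots by a seeded random
    pairing.  Excess demand duplicates uniformly chosen slots; demand on
    a group with no slots is dropped and accounted as lost.  Only
    excitatory presynaptic connections are rewired; the inhibitory
    subgraph is copied unchanged.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7472]))
    ref_ann = reference.mtypes_of_edges()
    cloud_ann = cloud.mtypes_of_edges()
    attr_cols = [c for c in ("synapse_count", "path_length_um") if c in ref_ann.columns]
    if not attr_cols:
        raise ValueError("reference connectome carries no connection attributes")

    inh_ref = ref_ann[ref_ann["pre_class"] == "INH"]
    exc_ref = ref_ann[ref_ann["pre_class"] == "EXC"]
    exc_cloud = cloud_ann[cloud_ann["pre_class"] == "EXC"]

    slot_groups = {k: g[attr_cols].to_numpy()
                   for k, g in exc_ref.groupby(["post_id", "pre_mtype"], sort=True)}

    placed_rows = []
    acc: dict[tuple[str, str], np.ndarray] = {}

    def bump(key, col, amt):
        if key not in acc:
            acc[key] = np.zeros(4, dtype=np.int64)  # required, placed, duplicated, lost
        acc[key][col] += amt

    for (post_id, pre_mtype), g in exc_cloud.groupby(["post_id", "pre_mtype"], sort=True):
        post_mtype = g["post_mtype"].iloc[0]
        key = (pre_mtype, post_mtype)
        demand = len(g)
        bump(key, 0, demand)
        slots = slot_groups.get((post_id, pre_mtype))
        if slots is None or len(slots) == 0:
            bump(key, 3, demand)
            continue
        n_s = len(slots)
        if demand <= n_s:
            chosen = rng.permutation(n_s)[:demand]
        else:
            extra = rng.integers(0, n_s, size=demand - n_s)
            chosen = np.concatenate([rng.permutation(n_s), extra])
            bump(key, 2, demand - n_s)
        attrs = slots[chosen]
        bump(key, 1, demand)
        block = pd.DataFrame({"pre_id": g["pre_id"].to_numpy(),
                              "post_id": post_id})
        for c, col in enumerate(attr_cols):
            block[col] = attrs[:, c]
        placed_rows.append(block)

    hybrid_exc = (pd.concat(placed_rows, ignore_index=True) if placed_rows
                  else pd.DataFrame(columns=["pre_id", "post_id", *attr_cols]))
    inh_part = inh_ref[["pre_id", "post_id", *attr_cols]]
    hybrid = pd.concat([hybrid_exc, inh_part], ignore_index=True)
    if "synapse_count" in hybrid.columns:
        hybrid["synapse_count"] = hybrid["synapse_count"].astype(np.int64)
    hybrid = hybrid.sort_values(["pre_id", "post_id"], ignore_index=True)

    report = pd.DataFrame(
        [(mi, mj, *vals) for (mi, mj), vals in sorted(acc.items())],
        columns=["pre_mtype", "post_mtype", "required", "placed", "duplicated", "lost"])
    return Connectome(hybrid, reference.neurons), LossReport(report)


def matched_removal(reference: Connectome, loss: LossReport, seed: int) -> Connectome:
    """Control circuit: remove from the reference exactly the number of
    (excitatory) connections per m-type combination that the transplant
    lost, so its macroconnectome equals the hybrid's."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6D72]))
    ann = reference.mtypes_of_edges()
    drop = np.zeros(len(ann), dtype=bool)
    for (mi, mj), n_lost in sorted(loss.lost_dict().items()):
        pool = np.flatnonzero((ann["pre_mtype"] == mi).to_numpy()
                              & (ann["post_mtype"] == mj).to_numpy()
                              & (ann["pre_class"] == "EXC").to_numpy())
        if n_lost > len(pool):
            raise ValueError(f"cannot remove {n_lost} edges from block {mi}->{mj} "
                             f"({len(pool)} available)")
        drop[rng.choice(pool, size=n_lost, replace=False)] = True
    kept = reference.edges.loc[~drop].reset_index(drop=True)
    return Connectome(kept, reference.neurons)


def shuffle_path_length(connectome: Connectome, seed: int) -> Connectome:
    """Permute path_length among connections with the same presynaptic
    m-type onto the same postsynaptic neuron (excitatory presynaptic
    connections only); every other attribute and all inhibitory edges
    are untouched."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7368]))
    ann = connectome.mtypes_of_edges()
    pl = ann["path_length_um"].to_numpy().copy()
    exc = (ann["pre_class"] == "EXC").to_numpy()
    ann_exc = ann[exc]
    for _, g in ann_exc.groupby(["post_id", "pre_mtype"], sort=True):
        idx = g.index.to_numpy()
        if len(idx) > 1:
            pl[idx] = pl[idx[rng.permutation(len(idx))]]
    out = connectome.edges.copy()
    out["path_length_um"] = pl
    return Connectome(out, connectome.neurons)
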