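"""Synthetic cortical-column generation.

Builds a layered cylindrical population of neurons partitioned into
morphological types (m-types), renders per-type axon/dendrite density
clouds on a regular 2D (lateral, depth) offset grid, draws per-neuron
morphological jitter (the source of within-type diversity), and wires a
reference connectome from instance-level axo-dendritic overlaps.

Geometry convention: density clouds live on a vertical plane through the
two somas.  The first axis is the signed lateral offset along the
inter-soma direction (µm), the second axis the signed depth offset Δy
(µm).  For a neuron pair the lateral offset is the non-negative
horizontal soma distance r = √(Δx² + Δz²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CloudComponent",
    "MtypeSpec",
    "CircuitSpec",
    "DensityGrid",
    "MorphologySet",
    "generate_neurons",
    "render_density",
    "auto_extent",
    "instantiate_morphologies",
    "pairwise_overlap",
    "sample_reference_connectome",
    "assign_connection_attributes",
    "default_circuit_spec",
]


# ---------------------------------------------------------------------------
# Specification types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CloudComponent:
    """One Gaussian component of an arbor density cloud.

    ``center`` is the (lateral, depth) offset of the component mean from
    the soma in µm; ``sigma`` the per-axis standard deviations in µm;
    ``weight`` the density mass (total arbor content) of the component.
    """

    center: tuple[float, float]
    sigma: tuple[float, float]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma[0] <= 0 or self.sigma[1] <= 0:
            raise ValueError("component sigma must be positive")
        if self.weight <= 0:
            raise ValueError("component weight must be positive")


@dataclass(frozen=True)
class MtypeSpec:
    name: str
    layer: str
    synapse_class: str  # "EXC" | "INH"
    fraction: float
    axon: tuple[CloudComponent, ...]
    dendrite: tuple[CloudComponent, ...]

    def __post_init__(self) -> None:
        if self.synapse_class not in ("EXC", "INH"):
            raise ValueError(f"synapse_class must be EXC or INH, got {self.synapse_class!r}")
        if not self.axon or not self.dendrite:
            raise ValueError(f"m-type {self.name}: empty cloud mixture")


@dataclass(frozen=True)
class CircuitSpec:
    """Parameters of a synthetic column.

    ``jitter`` (η, µm) is the std of the per-neuron 3D displacement of
    its morphology; it also sets the log-normal mass-scale spread via
    ``jitter_scale_ref`` (σ_log = η / η_ref).  η = 0 reproduces the
    type clouds exactly for every neuron.
    """

    n_neurons: int
    mtypes: tuple[MtypeSpec, ...]
    layer_intervals: dict[str, tuple[float, float]]
    column_radius: float = 230.0
    jitter: float = 20.0
    jitter_scale_ref: float = 50.0
    grid_bin: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mtypes:
            raise ValueError("empty m-type catalog")
        total = sum(m.fraction for m in self.mtypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"m-type fractions sum to {total}, expected 1")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        if self.grid_bin <= 0:
            raise ValueError("grid_bin must be positive")
        # layer intervals must be disjoint and tile the depth range
        ivals = sorted(self.layer_intervals.values())
        for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
            if a1 > b0 + 1e-9:
                raise ValueError("layer intervals overlap")
        for m in self.mtypes:
            if m.layer not in self.layer_intervals:
                raise ValueError(f"m-type {m.name}: unknown layer {m.layer!r}")

    @property
    def mtype_names(self) -> list[str]:
        return [m.name for m in self.mtypes]

    def mtype(self, name: str) -> MtypeSpec:
        for m in self.mtypes:
            if m.name == name:
                return m
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Density grids
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid:
    """2D arbor density on a regular (lateral, depth) offset grid.

    ``values[i, j]`` is the density mass in the bin whose center is at
    ``(lat0 + i*bin, depth0 + j*bin)`` µm relative to the soma.
    """

    values: np.ndarray
    bin: float
    lat0: float
    depth0: float
    m_type: str = ""
    component: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("density grid must be 2D")
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")

    @property
    def mass(self) -> float:
        return float(self.values.sum())

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        nl, nd = self.values.shape
        return (self.lat0 + self.bin * np.arange(nl),
                self.depth0 + self.bin * np.arange(nd))


def auto_extent(components: tuple[CloudComponent, ...] | list[CloudComponent],
                n_sigma: float = 5.0) -> tuple[tuple[float, float], tuple[float, float]]:
    """Bounding box covering ``n_sigma`` standard deviations of every component."""
    lat_lo = min(c.center[0] - n_sigma * c.sigma[0] for c in components)
    lat_hi = max(c.center[0] + n_sigma * c.sigma[0] for c in components)
    dep_lo = min(c.center[1] - n_sigma * c.sigma[1] for c in components)
    dep_hi = max(c.center[1] + n_sigma * c.sigma[1] for c in components)
    return (lat_lo, lat_hi), (dep_lo, dep_hi)


def render_density(components, grid_bin: float, extent=None,
                   m_type: str = "", component: str = "") -> DensityGrid:
    """Rasterize a Gaussian-mixture cloud onto a (lateral, depth) grid.

    Bin mass is the component density at the bin center times the bin
    area; with the default extent (5σ) the total grid mass matches the
    parameterized mass within 1%.
    """
    if grid_bin <= 0:
        raise ValueError("grid_bin must be positive")
    components = tuple(components)
    if not components:
        raise ValueError("empty cloud mixture")
    if extent is None:
        extent = auto_extent(components)
    (lat_lo, lat_hi), (dep_lo, dep_hi) = extent
    for c in components:
        for k, (lo, hi) in enumerate(((lat_lo, lat_hi), (dep_lo, dep_hi))):
            if c.center[k] - 4 * c.sigma[k] < lo - 1e-9 or c.center[k] + 4 * c.sigma[k] > hi + 1e-9:
                raise ValueError("extent must cover >= 4 sigma of every component")
    # bin centers snapped to integer multiples of the bin size so that
    # any two grids (and their convolution) share one lattice
    lat = np.arange(np.floor(lat_lo / grid_bin), np.ceil(lat_hi / grid_bin) + 1) * grid_bin
    dep = np.arange(np.floor(dep_lo / grid_bin), np.ceil(dep_hi / grid_bin) + 1) * grid_bin
    L, D = np.meshgrid(lat, dep, indexing="ij")
    vals = np.zeros_like(L)
    for c in components:
        g = np.exp(-0.5 * (((L - c.center[0]) / c.sigma[0]) ** 2
                           + ((D - c.center[1]) / c.sigma[1]) ** 2))
        vals += c.weight * g / (2 * np.pi * c.sigma[0] * c.sigma[1])
    vals *= grid_bin ** 2
    return DensityGrid(vals, grid_bin, float(lat[0]), float(dep[0]),
                       m_type=m_type, component=component)


# ---------------------------------------------------------------------------
# Neuron placement
# ---------------------------------------------------------------------------

def _largest_remainder_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` with counts ≈ fraction*total.

    Floors each target and hands the remaining units to the largest
    fractional parts; ties go to the earlier catalog entry.
    """
    target = fractions * total
    counts = np.floor(target).astype(int)
    remainder = target - counts
    short = total - counts.sum()
    # stable sort => earlier entries win ties
    order = np.argsort(-remainder, kind="stable")
    counts[order[:short]] += 1
    return counts


def generate_neurons(spec: CircuitSpec) -> pd.DataFrame:
    """Place neurons uniformly in the column cross-section and in depth
    within each m-type's layer interval.

    Returns a NeuronTable: DataFrame with columns (neuron_id, m_type,
    layer, synapse_class, x_um, y_um, z_um), ids contiguous from 0.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x6E65]))
    fractions = np.array([m.fraction for m in spec.mtypes])
    counts = _largest_remainder_counts(fractions, spec.n_neurons)
    rows = []
    for m, cnt in zip(spec.mtypes, counts):
        y0, y1 = spec.layer_intervals[m.layer]
        r = spec.column_radius * np.sqrt(rng.random(cnt))
        theta = rng.random(cnt) * 2 * np.pi
        y = y0 + (y1 - y0) * rng.random(cnt)
        rows.append(pd.DataFrame({
            "m_type": m.name,
            "layer": m.layer,
            "synapse_class": m.synapse_class,
            "x_um": r * np.cos(theta),
            "y_um": y,
            "z_um": r * np.sin(theta),
        }))
    table = pd.concat(rows, ignore_index=True)
    table.insert(0, "neuron_id", np.arange(len(table)))
    return table


# ---------------------------------------------------------------------------
# Morphological jitter
# ---------------------------------------------------------------------------

@dataclass
class MorphologySet:
    """Per-neuron realized cloud parameters.

    Each neuron's morphology is its type cloud displaced by
    ``displacement`` (3D, µm) and with density mass multiplied by
    ``scale``.  η = 0 gives zero displacement and unit scale.
    """

    displacement: np.ndarray  # (n, 3) µm
    scale: np.ndarray         # (n,)
    jitter: float

    def __len__(self) -> int:
        return len(self.scale)


def instantiate_morphologies(neurons: pd.DataFrame, spec: CircuitSpec) -> MorphologySet:
    """Draw per-neuron displacement ~ N(0, η²) per axis and mass scale
    ~ exp(N(0, (η/η_ref)²)).  Deterministic given ``spec.seed``."""
    n = len(neurons)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x6D6F]))
    if spec.jitter == 0:
        return MorphologySet(np.zeros((n, 3)), np.ones(n), 0.0)
    disp = rng.normal(0.0, spec.jitter, size=(n, 3))
    sigma_log = spec.jitter / spec.jitter_scale_ref
    scale = np.exp(rng.normal(0.0, sigma_log, size=n))
    return MorphologySet(disp, scale, spec.jitter)


# ---------------------------------------------------------------------------
# Overlap
# ---------------------------------------------------------------------------

def pairwise_overlap(axon: DensityGrid, dendrite: DensityGrid,
                     soma_offset: tuple[float, float]) -> float:
    """Overlap score of an axon cloud displaced by ``soma_offset``
    (pre-soma position relative to post-soma, (lateral, depth) µm)
    against a dendrite cloud: Σ_bins axon(u − Δ) · dendrite(u).

    Grids are aligned at nearest-bin resolution.
    """
    if abs(axon.bin - dendrite.bin) > 1e-12:
        raise ValueError("mismatched bin sizes")
    b = axon.bin
    # axon bin i sits at axon.lat0 + i*b + offset; dendrite bin j at dendrite.lat0 + j*b
    # match j = i + shift where shift = round((axon.lat0 + offset - dendrite.lat0)/b)
    sh_l = round((axon.lat0 + soma_offset[0] - dendrite.lat0) / b)
    sh_d = round((axon.depth0 + soma_offset[1] - dendrite.depth0) / b)
    na_l, na_d = axon.values.shape
    nd_l, nd_d = dendrite.values.shape
    a_lo_l, a_hi_l = max(0, -sh_l), min(na_l, nd_l - sh_l)
    a_lo_d, a_hi_d = max(0, -sh_d), min(na_d, nd_d - sh_d)
    if a_lo_l >= a_hi_l or a_lo_d >= a_hi_d:
        return 0.0
    a = axon.values[a_lo_l:a_hi_l, a_lo_d:a_hi_d]
    d = dendrite.values[a_lo_l + sh_l:a_hi_l + sh_l, a_lo_d + sh_d:a_hi_d + sh_d]
    return float(np.sum(a * d))


# ---------------------------------------------------------------------------
# Reference connectome
# ---------------------------------------------------------------------------

def _pair_offsets(pre_xyz: np.ndarray, post_xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(r, Δy) offsets for all (pre, post) combinations.

    r is the horizontal (xz) distance, Δy = y_pre − y_post; both shaped
    (n_pre, n_post).
    """
    dx = pre_xyz[:, 0][:, None] - post_xyz[:, 0][None, :]
    dz = pre_xyz[:, 2][:, None] - post_xyz[:, 2][None, :]
    dy = pre_xyz[:, 1][:, None] - post_xyz[:, 1][None, :]
    return np.hypot(dx, dz), dy


def _lookup_field(field_values: np.ndarray, bin_: float, lat0: float, depth0: float,
                  r: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Nearest-bin lookup of a field at offsets (r, dy); out of range -> 0."""
    il = np.rint((r - lat0) / bin_).astype(np.int64)
    jd = np.rint((dy - depth0) / bin_).astype(np.int64)
    nl, nd = field_values.shape
    ok = (il >= 0) & (il < nl) & (jd >= 0) & (jd < nd)
    out = np.zeros(r.shape, dtype=float)
    out[ok] = field_values[il[ok], jd[ok]]
    return out


def sample_reference_connectome(neurons: pd.DataFrame, morphologies: MorphologySet,
                                spec: CircuitSpec, targets: dict[tuple[str, str], int],
                                seed: int):
    """Wire the reference ("apposition-like") connectome.

    Per ordered m-type pair, selection probabilities are proportional to
    the square of the instance-level axo-dendritic overlap, and exactly
    ``targets[(pre_mtype, post_mtype)]`` distinct edges are drawn without
    replacement.  With the displacement + mass-scale jitter model the
    instance overlap factorizes as s_pre · s_post · F(Δsoma + δ_pre −
    δ_post) on the type-level overlap field F, so at η = 0 the selection
    probabilities coincide exactly with the cloud-wiring blocks.

    Returns a :class:`~cloudcircuit.wiring.Connectome`.
    """
    from .wiring import Connectome, _wire_blocks

    edges = _wire_blocks(neurons, spec, targets, seed, salt=0x7265,
                         displacement=morphologies.displacement,
                         scale=morphologies.scale)
    return Connectome(edges, neurons)


def assign_connection_attributes(connectome, neurons: pd.DataFrame,
                                 seed: int, tortuosity: float = 1.2,
                                 noise_sigma: float = 20.0,
                                 mean_synapses: float = 4.5):
    """Attach synapse_count and path_length to each edge.

    path_length = Euclidean soma distance × tortuosity + |N(0, σ)| (µm,
    half-normal, so the path is never shorter than the tortuous route);
    synapse_count = 1 + Poisson(mean_synapses − 1).

    Accepts a Connectome or a bare edge DataFrame and returns the same
    kind with the two attribute columns added.
    """
    if tortuosity < 1:
        raise ValueError("tortuosity must be >= 1")
    wrap = hasattr(connectome, "edges")
    edges = connectome.edges if wrap else connectome
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6174]))
    xyz = neurons.set_index("neuron_id")[["x_um", "y_um", "z_um"]]
    p0 = xyz.loc[edges["pre_id"]].to_numpy()
    p1 = xyz.loc[edges["post_id"]].to_numpy()
    dist = np.linalg.norm(p0 - p1, axis=1)
    noise = np.abs(rng.normal(0.0, noise_sigma, size=len(edges))) if noise_sigma > 0 else 0.0
    out = edges.copy()
    out["synapse_count"] = 1 + rng.poisson(max(mean_synapses - 1.0, 0.0), size=len(edges))
    out["path_length_um"] = dist * tortuosity + noise
    return connectome.with_edges(out) if wrap else out


# ---------------------------------------------------------------------------
# Default study configuration
# ---------------------------------------------------------------------------

def default_circuit_spec(n_neurons: int = 2000, jitter: float = 20.0,
                         seed: int = 0, grid_bin: float = 2.0) -> CircuitSpec:
    """Two-layer, five-m-type synthetic column used throughout.

    Upper layer (depth 0–400 µm): one excitatory and one inhibitory
    type; lower layer (400–900 µm): two excitatory types and one
    inhibitory type.  Excitatory axons project across layers (downward
    or upward lobes); dendrites are more compact — a cartoon of
    pyramidal-cell geometry sufficient to give distance- and
    layer-dependent connectivity.
    """
    def comp(clat, cdep, slat, sdep, w=1.0):
        return CloudComponent((clat, cdep), (slat, sdep), w)

    mtypes = (
        MtypeSpec("L1E", "upper", "EXC", 0.30,
                  axon=(comp(0, -150, 60, 120, 0.6), comp(0, 30, 50, 60, 0.4)),
                  dendrite=(comp(0, 20, 40, 60),)),
        MtypeSpec("L1I", "upper", "INH", 0.10,
                  axon=(comp(0, 0, 50, 60),),
                  dendrite=(comp(0, 0, 45, 55),)),
        MtypeSpec("L2E1", "lower", "EXC", 0.30,
                  axon=(comp(0, 150, 60, 130, 0.5), comp(0, -20, 55, 70, 0.5)),
                  dendrite=(comp(0, -30, 45, 80),)),
        MtypeSpec("L2E2", "lower", "EXC", 0.20,
                  axon=(comp(0, 0, 70, 90),),
                  dendrite=(comp(0, 10, 50, 70),)),
        MtypeSpec("L2I", "lower", "INH", 0.10,
                  axon=(comp(0, 0, 55, 65),),
                  dendrite=(comp(0, 0, 50, 60),)),
    )
    return CircuitSpec(
        n_neurons=n_neurons,
        mtypes=mtypes,
        layer_intervals={"upper": (0.0, 400.0), "lower": (400.0, 900.0)},
        column_radius=230.0,
        jitter=jitter,
        grid_bin=grid_bin,
        seed=seed,
    )


def default_targets(neurons: pd.DataFrame, spec: CircuitSpec,
                    mean_degree: float = 40.0) -> dict[tuple[str, str], int]:
    """Per-m-type-pair edge targets for the default circuit.

    The total edge budget mean_degree × n is split across ordered
    m-type pairs proportionally to the summed squared type-level
    overlap of the block (so strongly overlapping type pairs get more
    connections), with largest-remainder rounding.  Deterministic.
    """
    from .wiring import convolve_clouds

    type_grids = {m.name: (render_density(m.axon, spec.grid_bin),
                           render_density(m.dendrite, spec.grid_bin))
                  for m in spec.mtypes}
    xyz = neurons[["x_um", "y_um", "z_um"]].to_numpy()
    by_type = {m: np.flatnonzero((neurons["m_type"] == m).to_numpy())
               for m in spec.mtype_names}
    names = spec.mtype_names
    weights, keys, capacity = [], [], []
    for mi in names:
        for mj in names:
            F = convolve_clouds(type_grids[mj][1], type_grids[mi][0])
            r, dy = _pair_offsets(xyz[by_type[mi]], xyz[by_type[mj]])
            O = _lookup_field(F.values, F.bin, F.lat0, F.depth0, r, dy)
            if mi == mj:
                np.fill_diagonal(O, 0.0)
            keys.append((mi, mj))
            weights.append(float(np.sum(O ** 2)))
            capacity.append(int(np.count_nonzero(O)))
    weights = np.array(weights)
    total_edges = int(round(mean_degree * len(neurons)))
    counts = _largest_remainder_counts(weights / weights.sum(), total_edges)
    counts = np.minimum(counts, capacity)  # clip to feasible block capacity
    return {k: int(c) for k, c in zip(keys, counts) if c > 0}
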