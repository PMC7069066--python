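"""File formats, configuration, and the end-to-end pipeline.

Artifacts are plain text: NeuronTable and Connectome as TSV with
headers, adjacency optionally as Matrix Market coordinate format,
DensityGrid as a delimited matrix with a JSON sidecar, SpikeData as
one two-column (time_ms, neuron_id) file per trial, and reports as
JSON.  ``run_pipeline`` orchestrates the full comparison: generate a
circuit, wire the reference and cloud connectomes, transplant, build
the matched-removal control, compute structural statistics, simulate
all three variants, and analyze the activity — deterministically for a
given config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity, compare, topology
from .circuit import (CircuitSpec, default_circuit_spec, default_targets,
                      assign_connection_attributes, generate_neurons,
                      instantiate_morphologies, sample_reference_connectome)
from .simulate import (SimParams, SpikeData, build_stimulus, pulsed_envelope,
                       simulate)
from .wiring import (Connectome, LossReport, build_cloud_connectome,
                     matched_removal, shuffle_path_length, transplant)

__all__ = [
    "NEURON_COLUMNS",
    "write_neurons", "read_neurons",
    "write_connectome", "read_connectome", "write_adjacency_mm",
    "write_density_grid", "read_density_grid",
    "write_spikes", "read_spikes",
    "write_loss_report", "read_loss_report",
    "PipelineConfig", "load_config", "run_pipeline",
    "run_simplex_correlation_study",
]

SCHEMA_VERSION = 1

NEURON_COLUMNS = ["neuron_id", "m_type", "layer", "synapse_class",
                  "x_um", "y_um", "z_um"]
EDGE_COLUMNS = ["pre_id", "post_id", "synapse_count", "path_length_um"]


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def _check_header(found, expected, path) -> None:
    missing = [c for c in expected if c not in found]
    if missing:
        raise ValueError(f"{path}: malformed header, missing column(s) "
                         f"{', '.join(missing)}")


def write_neurons(neurons: pd.DataFrame, path) -> None:
    neurons[NEURON_COLUMNS].to_csv(path, sep="\t", index=False)


def read_neurons(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_header(df.columns, NEURON_COLUMNS, path)
    return df[NEURON_COLUMNS]


def write_connectome(connectome: Connectome, path) -> None:
    cols = [c for c in EDGE_COLUMNS if c in connectome.edges.columns]
    connectome.edges[cols].to_csv(path, sep="\t", index=False)


def read_connectome(path, neurons: pd.DataFrame) -> Connectome:
    df = pd.read_csv(path, sep="\t")
    _check_header(df.columns, ["pre_id", "post_id"], path)
    return Connectome(df, neurons)


def write_adjacency_mm(connectome: Connectome, path) -> None:
    """Binary adjacency as Matrix Market coordinate format (one nonzero
    per edge)."""
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    n = connectome.n_neurons
    e = connectome.edges
    m = coo_matrix((np.ones(len(e), dtype=np.int8),
                    (e["pre_id"].to_numpy(), e["post_id"].to_numpy())),
                   shape=(n, n))
    mmwrite(str(path), m)


def write_density_grid(grid, path) -> None:
    path = Path(path)
    np.savetxt(path, grid.values, delimiter="\t")
    meta = {"bin_um": grid.bin, "lat0_um": grid.lat0, "depth0_um": grid.depth0,
            "m_type": grid.m_type, "component": grid.component,
            "schema_version": SCHEMA_VERSION}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_density_grid(path):
    from .circuit import DensityGrid

    path = Path(path)
    vals = np.loadtxt(path, delimiter="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return DensityGrid(vals, meta["bin_um"], meta["lat0_um"], meta["depth0_um"],
                       m_type=meta.get("m_type", ""), component=meta.get("component", ""))


def write_spikes(spikes: SpikeData, directory, prefix: str = "trial") -> list[Path]:
    """One whitespace-delimited (time_ms, neuron_id) file per trial,
    plus a JSON protocol sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(spikes.n_trials):
        p = directory / f"{prefix}_{k:03d}.gdf"
        np.savetxt(p, np.column_stack([spikes.times[k], spikes.ids[k]]),
                   fmt=["%.3f", "%d"])
        paths.append(p)
    meta = {"duration_ms": spikes.duration, "n_neurons": spikes.n_neurons,
            "n_trials": spikes.n_trials, "protocol": spikes.protocol,
            "schema_version": SCHEMA_VERSION}
    (directory / f"{prefix}_protocol.json").write_text(json.dumps(meta, indent=1))
    return paths


def read_spikes(directory, prefix: str = "trial") -> SpikeData:
    directory = Path(directory)
    meta = json.loads((directory / f"{prefix}_protocol.json").read_text())
    times, ids = [], []
    for k in range(meta["n_trials"]):
        data = np.loadtxt(directory / f"{prefix}_{k:03d}.gdf", ndmin=2)
        if data.size == 0:
            data = np.empty((0, 2))
        times.append(data[:, 0])
        ids.append(data[:, 1].astype(np.int64))
    return SpikeData(times, ids, meta["duration_ms"], meta["n_neurons"],
                     meta.get("protocol", {}))


def write_loss_report(loss: LossReport, path) -> None:
    payload = {"schema_version": SCHEMA_VERSION,
               "excitatory_loss_fraction": loss.excitatory_loss_fraction,
               "table": loss.table.to_dict(orient="records")}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_loss_report(path) -> LossReport:
    payload = json.loads(Path(path).read_text())
    return LossReport(pd.DataFrame(payload["table"],
                                   columns=["pre_mtype", "post_mtype", "required",
                                            "placed", "duplicated", "lost"]))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one run needs; see docs for the schema.  All
    randomness derives from ``seed``."""

    n_neurons: int = 800
    jitter: float = 20.0
    grid_bin: float = 2.0
    mean_degree: float = 40.0
    transfer_exponent: float = 2.0
    seed: int = 0
    simulate_activity: bool = True
    sim: SimParams = field(default_factory=lambda: SimParams(duration=1000.0, trials=3))
    stimulus_fibers: int = 0            # 0 = spontaneous protocol only
    stimulus_rate_per_ms: float = 0.05
    analysis_dt: float = 20.0
    reliability_sigma: float = 5.0
    distance_bin: float = 20.0
    max_simplex_dim: int = 3
    out_dir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    version = raw.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema_version {version}")
    sim_raw = raw.pop("sim", None)
    cfg = PipelineConfig(**raw)
    if sim_raw:
        cfg.sim = SimParams(**sim_raw)
    return cfg


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full comparison and return the RunReport dict.

    Stages: generate circuit → wire reference → wire cloud →
    transplant → matched-removal control → topology & first-order
    comparison → simulate the three variants → activity analysis.
    If ``config.out_dir`` is set, artifacts are written there.
    """
    report: dict = {"schema_version": SCHEMA_VERSION,
                    "config_hash": config.config_hash(),
                    "seed": config.seed, "stages": {}, "warnings": []}

    def stage(name):
        s = _stage_seed(config.seed, name)
        report["stages"][name] = {"seed": s}
        return s, report["stages"][name]

    # --- circuit -----------------------------------------------------------
    s, info = stage("generate")
    spec = default_circuit_spec(n_neurons=config.n_neurons, jitter=config.jitter,
                                seed=s, grid_bin=config.grid_bin)
    neurons = generate_neurons(spec)
    morph = instantiate_morphologies(neurons, spec)
    info["n_neurons"] = len(neurons)
    info["mtypes"] = spec.mtype_names

    # --- reference wiring --------------------------------------------------
    s, info = stage("wire_reference")
    targets = default_targets(neurons, spec, mean_degree=config.mean_degree)
    reference = sample_reference_connectome(neurons, morph, spec, targets, s)
    reference = assign_connection_attributes(reference, neurons, s)
    info["n_edges"] = reference.n_edges

    # --- cloud wiring ------------------------------------------------------
    s, info = stage("wire_cloud")
    cloud = build_cloud_connectome(reference, spec, s,
                                   exponent=config.transfer_exponent)
    info["n_edges"] = cloud.n_edges

    # --- transplant and control -------------------------------------------
    s, info = stage("transplant")
    hybrid, loss = transplant(cloud, reference, s)
    info["n_edges"] = hybrid.n_edges
    info["excitatory_loss_fraction"] = loss.excitatory_loss_fraction

    s, info = stage("control")
    control = shuffle_path_length(matched_removal(reference, loss, s), s)
    info["n_edges"] = control.n_edges

    variants = {"reference": reference, "cloud": hybrid, "control": control}

    # --- topology ----------------------------------------------------------
    s, info = stage("topology")
    for name, conn in variants.items():
        summ = topology.degree_summary(conn)
        counts = topology.count_simplices(conn, max_dim=config.max_simplex_dim)
        info[name] = {"sigma_in": summ.sigma_in, "sigma_out": summ.sigma_out,
                      "simplex_counts": counts}
    # identity regime: reference/cloud degree sigmas indistinguishable
    # (normal-theory SE of a standard deviation: sigma / sqrt(2(n-1)))
    se = ((info["reference"]["sigma_in"] ** 2 + info["cloud"]["sigma_in"] ** 2)
          / (2.0 * (len(neurons) - 1))) ** 0.5
    if abs(info["reference"]["sigma_in"] - info["cloud"]["sigma_in"]) < 2.0 * se:
        info["identity_regime"] = True

    # --- first-order comparison -------------------------------------------
    s, info = stage("compare")
    diff = compare.macroconnectome_diff(compare.macroconnectome(reference),
                                        compare.macroconnectome(cloud))
    info["macroconnectome_max_abs_diff"] = int(np.abs(diff.to_numpy()).max())
    kls = {}
    for layer in sorted(neurons["layer"].unique()):
        ref_d = compare.connection_distance_distribution(
            reference, "afferent", "layer", layer,
            bin_width=config.distance_bin, max_distance=1200.0)
        cld_d = compare.connection_distance_distribution(
            hybrid, "afferent", "layer", layer,
            bin_width=config.distance_bin, max_distance=1200.0)
        kls[layer] = compare.kl_divergence(ref_d, cld_d)
    info["kl_afferent"] = kls
    info["reciprocity_reference"] = compare.reciprocal_overexpression(reference)
    info["reciprocity_cloud"] = compare.reciprocal_overexpression(hybrid)

    # --- activity ----------------------------------------------------------
    if config.simulate_activity:
        s, info = stage("simulate")
        stim = None
        if config.stimulus_fibers > 0:
            stim = build_stimulus(neurons, config.stimulus_fibers,
                                  config.stimulus_rate_per_ms,
                                  config.sim.n_bins, s)
        rasters = {name: simulate(conn, config.sim, stim, s)
                   for name, conn in variants.items()}
        for name, sp in rasters.items():
            info[name] = {"total_spikes": sp.total_spikes()}

        s, info = stage("analyze_activity")
        for name, sp in rasters.items():
            fr = activity.firing_rates(sp, config.analysis_dt)
            entry = {"mean_rate_hz": fr.mean_rate_hz}
            ei = activity.ei_spike_ratio(sp, neurons)
            entry["ei_ratio"] = None if np.isnan(ei.pooled) else ei.pooled
            if sp.n_trials >= 2:
                tc = activity.population_trial_correlations(sp, dt=5.0)
                entry["trial_correlation"] = tc.mean
                entry["trial_pairs"] = tc.n_pairs
            info[name] = entry

    # --- artifacts ---------------------------------------------------------
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_neurons(neurons, out / "neurons.tsv")
        for name, conn in variants.items():
            write_connectome(conn, out / f"connectome_{name}.tsv")
        write_loss_report(loss, out / "loss_report.json")
        if config.simulate_activity:
            for name, sp in rasters.items():
                write_spikes(sp, out / f"spikes_{name}")
        (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


# ---------------------------------------------------------------------------
# Simplex-correlation study (evoked protocol)
# ---------------------------------------------------------------------------

def _profile_summary(profile, min_pairs: int) -> dict:
    """Slope of the per-dimension overall mean correlation versus
    dimension, and the count-weighted pooled sink/source means, over
    dimensions >= 2 with at least ``min_pairs`` pair observations."""
    dims = [d for d in sorted(profile.position_means)
            if d >= 2 and profile.position_counts[d].sum() >= min_pairs]
    if len(dims) < 2:
        raise ValueError("fewer than 2 populated simplex dimensions")
    means = np.array([profile.overall_mean(d) for d in dims])
    slope = float(np.polyfit(dims, means, 1)[0])
    s_sum = s_n = k_sum = k_n = 0.0
    for d in dims:
        m, c = profile.position_means[d], profile.position_counts[d]
        s_sum += m[0] * c[0]
        s_n += c[0]
        k_sum += m[-1] * c[-1]
        k_n += c[-1]
    source, sink = s_sum / s_n, k_sum / k_n
    return {"dims": dims, "means": means.tolist(), "slope": slope,
            "source_mean": float(source), "sink_mean": float(sink),
            "sink_source_gap": float(sink - source)}


def run_simplex_correlation_study(seed: int, n_neurons: int = 500,
                                  mean_degree: float = 30.0,
                                  jitter: float = 20.0, gamma: float = 1.15,
                                  trials: int = 20, duration: float = 2000.0,
                                  max_dim: int = 5, min_pairs: int = 20,
                                  include_cloud: bool = False) -> dict:
    """Evoked-activity study of pair correlations by position in
    maximal simplices, on one seeded circuit realization.

    Wires the reference connectome, simulates a pulsed-fiber evoked
    protocol, computes the Δt = 20 ms correlation matrix over the
    concatenated trials, and summarizes the maximal-simplex position
    profile (mean correlation per dimension, its slope versus
    dimension, and the pooled sink-minus-source gap).  With
    ``include_cloud`` the cloud connectome is transplanted and analyzed
    the same way for the gap comparison.
    """
    spec = default_circuit_spec(n_neurons=n_neurons, jitter=jitter, seed=seed)
    neurons = generate_neurons(spec)
    morph = instantiate_morphologies(neurons, spec)
    targets = default_targets(neurons, spec, mean_degree=mean_degree)
    reference = sample_reference_connectome(neurons, morph, spec, targets, seed)
    reference = assign_connection_attributes(reference, neurons, seed)

    params = SimParams(duration=duration, trials=trials, gamma=gamma)
    env = pulsed_envelope(params.n_bins, params.dt)
    stim = build_stimulus(neurons, 25, env, params.n_bins, seed)

    def analyze(conn: Connectome) -> dict:
        _, maximal = topology.count_maximal_simplices(conn, max_dim=max_dim)
        spikes = simulate(conn, params, stimulus=stim, seed=seed)
        R = activity.pairwise_correlation_matrix(spikes, dt=20.0)
        prof = activity.simplex_position_correlations(R, maximal)
        out = _profile_summary(prof, min_pairs)
        out["mean_rate_hz"] = spikes.total_spikes() / len(neurons) / trials \
            / (duration / 1000.0)
        return out

    result = {"seed": seed, "reference": analyze(reference)}
    if include_cloud:
        cloud = build_cloud_connectome(reference, spec, seed)
        hybrid, _ = transplant(cloud, reference, seed)
        result["cloud"] = analyze(hybrid)
        result["gap_shrinks_in_cloud"] = (
            abs(result["cloud"]["sink_source_gap"])
            < abs(result["reference"]["sink_source_gap"]))
    return result
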