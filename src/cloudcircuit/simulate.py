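"""Stochastic spiking-network simulation.

A discrete-time GLM-style hazard model that consumes any connectome
and produces multi-trial spike rasters.  Each neuron spikes in a time
bin with probability h = 1 − exp(−exp(bias + drive)·Δt), where the
drive is the exponentially filtered sum of delayed synaptic inputs
(weight × synapse count × class gain).  A scalar excitability knob γ
scales excitatory and inhibitory gains differentially (g_E = γ^1.7,
g_I = γ by default), emulating how raising extracellular calcium moves
such circuits from asynchronous towards synchronous firing.  Synaptic
delays derive from each connection's axonal path length divided by a
conduction velocity.

This is deliberately a phenomenological stand-in for multicompartment
simulation: only directions and orderings of effects are meaningful,
never absolute firing-rate magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .wiring import Connectome

__all__ = ["SimParams", "StimulusSet", "SpikeData", "build_stimulus",
           "pulsed_envelope", "simulate"]


def pulsed_envelope(n_bins: int, dt: float, baseline: float = 0.005,
                    pulse_rate: float = 0.15, pulse_ms: float = 20.0,
                    period_ms: float = 100.0) -> np.ndarray:
    """Stimulus rate envelope (spikes/ms per fiber): a baseline with
    periodic rectangular pulses, starting at t = 0."""
    if n_bins < 1 or dt <= 0 or period_ms <= 0 or pulse_ms <= 0:
        raise ValueError("invalid envelope parameters")
    env = np.full(n_bins, float(baseline))
    period = max(1, int(round(period_ms / dt)))
    width = max(1, int(round(pulse_ms / dt)))
    for start in range(0, n_bins, period):
        env[start:start + width] = pulse_rate
    return env


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters (times in ms, lengths in µm).

    ``bias_exc``/``bias_inh`` are log baseline hazards per ms (−6 ≈
    2.5 Hz).  ``w_exc`` (> 0) and ``w_inh`` (< 0) are drive increments
    per synapse per presynaptic spike before the γ-dependent gain.
    """

    dt: float = 1.0
    duration: float = 2000.0
    trials: int = 5
    bias_exc: float = -6.0
    bias_inh: float = -5.5
    w_exc: float = 0.09
    w_inh: float = -0.25
    gamma: float = 1.0
    gain_exc_exponent: float = 1.7
    tau_syn: float = 5.0
    refractory: float = 3.0
    conduction_velocity: float = 300.0
    stim_weight: float = 1.2

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.trials < 1:
            raise ValueError("at least one trial")
        if self.w_exc <= 0 or self.w_inh >= 0:
            raise ValueError("w_exc must be positive and w_inh negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    def g_exc(self, gamma: float | None = None) -> float:
        g = self.gamma if gamma is None else gamma
        return g ** self.gain_exc_exponent

    def g_inh(self, gamma: float | None = None) -> float:
        g = self.gamma if gamma is None else gamma
        return g

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class StimulusSet:
    """Thalamic-like input: fibers on a lateral grid, each innervating
    the neurons within a radius, firing a frozen spike train (the same
    stimulus is replayed on every trial)."""

    fiber_xz: np.ndarray                 # (F, 2) µm
    innervation: list[np.ndarray]        # neuron indices per fiber
    spike_bins: list[np.ndarray]         # spike time-bin indices per fiber
    radius: float
    n_bins: int

    @property
    def n_fibers(self) -> int:
        return len(self.fiber_xz)

    def total_events(self) -> int:
        return int(sum(len(s) for s in self.spike_bins))


def build_stimulus(neurons: pd.DataFrame, n_fibers: int, rate_per_ms,
                   n_bins: int, seed: int, radius: float = 60.0,
                   column_radius: float = 230.0) -> StimulusSet:
    """Place ``n_fibers`` input fibers on a lateral grid across the
    column and draw one frozen Poisson spike train per fiber from the
    rate envelope (scalar, or per-bin array in spikes/ms)."""
    if n_fibers < 1:
        raise ValueError("need at least one fiber")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7374]))
    side = int(np.ceil(np.sqrt(n_fibers)))
    grid = np.linspace(-column_radius, column_radius, side)
    gx, gz = np.meshgrid(grid, grid)
    fiber_xz = np.column_stack([gx.ravel(), gz.ravel()])[:n_fibers]
    xz = neurons[["x_um", "z_um"]].to_numpy()
    innervation = []
    for f in fiber_xz:
        d = np.hypot(xz[:, 0] - f[0], xz[:, 1] - f[1])
        innervation.append(np.flatnonzero(d <= radius))
    if all(len(v) == 0 for v in innervation):
        warnings.warn("stimulus innervates no neurons", stacklevel=2)
    env = np.broadcast_to(np.asarray(rate_per_ms, dtype=float), (n_bins,))
    if np.any(env < 0):
        raise ValueError("rates must be non-negative")
    spike_bins = []
    for _ in range(n_fibers):
        counts = rng.poisson(env)
        spike_bins.append(np.flatnonzero(counts > 0))
    return StimulusSet(fiber_xz, innervation, spike_bins, radius, n_bins)


@dataclass
class SpikeData:
    """Multi-trial spike raster: per trial, parallel arrays of spike
    times (ms) and neuron ids, time-sorted."""

    times: list[np.ndarray]
    ids: list[np.ndarray]
    duration: float
    n_neurons: int
    protocol: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.times)

    def counts(self, trial: int | None = None) -> np.ndarray:
        """Spike count per neuron (summed over trials by default)."""
        out = np.zeros(self.n_neurons, dtype=np.int64)
        rng_ = range(self.n_trials) if trial is None else [trial]
        for k in rng_:
            np.add.at(out, self.ids[k], 1)
        return out

    def total_spikes(self) -> int:
        return int(sum(len(t) for t in self.times))


def simulate(connectome: Connectome, params: SimParams,
             stimulus: StimulusSet | None = None, seed: int = 0) -> SpikeData:
    """Run ``params.trials`` trials of the hazard model on a connectome.

    Trials share the connectome and the (frozen) stimulus but use
    independent noise streams; everything is deterministic given
    ``seed``.  Spike times respect the refractory period and lie in
    [0, duration).
    """
    neurons = connectome.neurons
    n = len(neurons)
    is_exc = (neurons["synapse_class"] == "EXC").to_numpy()
    bias = np.where(is_exc, params.bias_exc, params.bias_inh)

    e = connectome.edges
    pre = e["pre_id"].to_numpy()
    post = e["post_id"].to_numpy()
    syn = e["synapse_count"].to_numpy() if "synapse_count" in e.columns else np.ones(len(e))
    if "path_length_um" in e.columns:
        delay = e["path_length_um"].to_numpy() / params.conduction_velocity
    else:
        delay = np.full(len(e), params.dt)
    delay_bins = np.maximum(1, np.rint(delay / params.dt).astype(np.int64))
    g_e, g_i = params.g_exc(), params.g_inh()
    w = np.where(is_exc[pre], params.w_exc * g_e, params.w_inh * g_i) * syn

    # group edges by presynaptic neuron for fast propagation
    order = np.argsort(pre, kind="stable")
    pre_s, post_s, w_s, db_s = pre[order], post[order], w[order], delay_bins[order]
    starts = np.searchsorted(pre_s, np.arange(n + 1))

    n_bins = params.n_bins
    decay = np.exp(-params.dt / params.tau_syn)
    refrac_bins = int(np.ceil(params.refractory / params.dt))
    max_delay = int(db_s.max()) if len(db_s) else 1
    ring_len = max_delay + 2

    # frozen stimulus contributions per time bin
    stim_events: dict[int, list[int]] = {}
    if stimulus is not None:
        for f, bins in enumerate(stimulus.spike_bins):
            for b in bins:
                stim_events.setdefault(int(b), []).append(f)
        stim_gain = params.stim_weight * g_e

    trial_seeds = np.random.SeedSequence([int(seed), 0x73696D]).spawn(params.trials)
    all_times, all_ids = [], []
    for k in range(params.trials):
        rng = np.random.default_rng(trial_seeds[k])
        s_trace = np.zeros(n)
        incoming = np.zeros((ring_len, n))
        refrac = np.zeros(n, dtype=np.int64)
        t_list, i_list = [], []
        for t in range(n_bins):
            slot = t % ring_len
            s_trace = s_trace * decay + incoming[slot]
            incoming[slot] = 0.0
            if stimulus is not None and t in stim_events:
                tgt = (t + 1) % ring_len
                for f in stim_events[t]:
                    idx = stimulus.innervation[f]
                    if len(idx):
                        incoming[tgt, idx] += stim_gain
            hazard = 1.0 - np.exp(-np.exp(bias + s_trace) * params.dt)
            spikes = (rng.random(n) < hazard) & (refrac <= 0)
            refrac -= 1
            if spikes.any():
                sp = np.flatnonzero(spikes)
                refrac[sp] = refrac_bins
                t_list.append(np.full(len(sp), t * params.dt))
                i_list.append(sp)
                for v in sp:
                    a, b = starts[v], starts[v + 1]
                    if a == b:
                        continue
                    slots = (t + db_s[a:b]) % ring_len
                    np.add.at(incoming, (slots, post_s[a:b]), w_s[a:b])
        if t_list:
            all_times.append(np.concatenate(t_list))
            all_ids.append(np.concatenate(i_list))
        else:
            all_times.append(np.array([]))
            all_ids.append(np.array([], dtype=np.int64))
    protocol = {"seed": int(seed), "gamma": params.gamma,
                "stimulus": stimulus is not None, "dt": params.dt}
    return SpikeData(all_times, all_ids, params.duration, n, protocol)
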