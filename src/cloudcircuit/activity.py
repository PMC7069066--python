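"""Spike-train analytics.

Firing rates, E/I spike ratios, PSTH-based pairwise correlation
matrices, within/between-model trial correlations, spike-time
reliability (Gaussian-filtered inner products across trials), spatial
cluster correlations with an exponential distance fit, and the
simplex-position analyses relating pair correlations to where a
connection sits inside directed cliques.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SpikeData
from .topology import ParticipationRecord

__all__ = [
    "RateHistogram",
    "CorrelationMatrix",
    "ReliabilityResult",
    "ExpFitResult",
    "SimplexCorrelationProfile",
    "firing_rates",
    "ei_spike_ratio",
    "pairwise_correlation_matrix",
    "population_trial_correlations",
    "spike_time_reliability",
    "spatial_cluster_correlations",
    "fit_exponential",
    "simplex_position_correlations",
    "correlation_by_participation",
    "depth_profile",
]


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

@dataclass
class RateHistogram:
    bin_width: float            # ms
    rates_hz: np.ndarray        # per-bin population rate, Hz per neuron
    counts: np.ndarray          # raw spike counts per bin (all trials)
    n_neurons: int
    n_trials: int

    @property
    def mean_rate_hz(self) -> float:
        total_ms = self.bin_width * len(self.counts) * self.n_trials
        return float(self.counts.sum() / self.n_neurons / total_ms * 1000.0)


def firing_rates(spikes: SpikeData, dt: float, population: np.ndarray | None = None
                 ) -> RateHistogram:
    """Population rate histogram: spike count per Δt bin divided by Δt
    (and by the population size), averaged over trials."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    pop = np.arange(spikes.n_neurons) if population is None else np.asarray(population)
    if pop.size == 0:
        raise ValueError("empty population")
    member = np.zeros(spikes.n_neurons, dtype=bool)
    member[pop] = True
    nbins = int(np.ceil(spikes.duration / dt))
    counts = np.zeros(nbins, dtype=np.int64)
    for t, i in zip(spikes.times, spikes.ids):
        sel = member[i]
        if sel.any():
            b = np.minimum((t[sel] / dt).astype(np.int64), nbins - 1)
            np.add.at(counts, b, 1)
    per_bin_hz = counts / spikes.n_trials / pop.size / (dt / 1000.0)
    return RateHistogram(dt, per_bin_hz, counts, int(pop.size), spikes.n_trials)


@dataclass
class EIRatio:
    per_trial: np.ndarray       # NaN where a trial has no inhibitory spikes
    pooled: float


def ei_spike_ratio(spikes: SpikeData, neurons: pd.DataFrame) -> EIRatio:
    """Total excitatory spike count divided by total inhibitory spike
    count, per trial and pooled over trials."""
    is_exc = np.zeros(spikes.n_neurons, dtype=bool)
    is_exc[neurons.loc[neurons["synapse_class"] == "EXC", "neuron_id"]] = True
    ratios = np.empty(spikes.n_trials)
    e_tot = i_tot = 0
    for k in range(spikes.n_trials):
        e = int(is_exc[spikes.ids[k]].sum())
        i = len(spikes.ids[k]) - e
        e_tot += e
        i_tot += i
        ratios[k] = e / i if i > 0 else np.nan
    if i_tot == 0:
        warnings.warn("no inhibitory spikes; E/I ratio undefined", stacklevel=2)
        return EIRatio(ratios, float("nan"))
    return EIRatio(ratios, e_tot / i_tot)


# ---------------------------------------------------------------------------
# PSTHs and correlations
# ---------------------------------------------------------------------------

def _binned(spikes: SpikeData, dt: float) -> np.ndarray:
    """Per-neuron spike-count time series, trials concatenated:
    (n_neurons, n_trials · n_bins)."""
    nbins = int(np.ceil(spikes.duration / dt))
    X = np.zeros((spikes.n_neurons, spikes.n_trials * nbins))
    for k in range(spikes.n_trials):
        b = np.minimum((spikes.times[k] / dt).astype(np.int64), nbins - 1)
        np.add.at(X, (spikes.ids[k], k * nbins + b), 1.0)
    return X


@dataclass
class CorrelationMatrix:
    """Normalized PSTH covariance R_ij = C_ij / √(C_ii·C_jj) of the
    active (nonzero-variance) neurons."""

    ids: np.ndarray
    R: np.ndarray
    excluded: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        self._pos = {int(i): k for k, i in enumerate(self.ids)}

    def value(self, i: int, j: int) -> float:
        a, b = self._pos.get(int(i)), self._pos.get(int(j))
        if a is None or b is None:
            return float("nan")
        return float(self.R[a, b])


def pairwise_correlation_matrix(spikes: SpikeData, dt: float = 20.0) -> CorrelationMatrix:
    """Correlation coefficients of per-neuron PSTHs over the
    concatenated trials (Δt bins).  Neurons whose PSTH has zero
    variance are excluded and reported."""
    X = _binned(spikes, dt)
    var = X.var(axis=1)
    active = np.flatnonzero(var > 0)
    if len(active) < 2:
        raise ValueError("fewer than 2 active neurons")
    R = np.corrcoef(X[active])
    return CorrelationMatrix(active, R, np.flatnonzero(var == 0), dt)


@dataclass
class TrialCorrelation:
    mean: float
    n_pairs: int
    values: np.ndarray


def population_trial_correlations(spikes_a: SpikeData, dt: float = 5.0,
                                  spikes_b: SpikeData | None = None) -> TrialCorrelation:
    """Mean correlation of per-trial population PSTHs.

    Within one model (``spikes_b`` omitted): all K(K−1)/2 unordered
    pairs of distinct trials.  Between two models: all K(K+1)/2
    unordered index pairs including equal indices.
    """
    def trial_psths(sp: SpikeData) -> np.ndarray:
        nbins = int(np.ceil(sp.duration / dt))
        P = np.zeros((sp.n_trials, nbins))
        for k in range(sp.n_trials):
            b = np.minimum((sp.times[k] / dt).astype(np.int64), nbins - 1)
            np.add.at(P[k], b, 1.0)
        return P

    A = trial_psths(spikes_a)

    def corr(x, y):
        if x.std() == 0 or y.std() == 0:
            return np.nan
        return np.corrcoef(x, y)[0, 1]

    if spikes_b is None:
        K = len(A)
        if K < 2:
            raise ValueError("need at least 2 trials")
        vals = np.array([corr(A[k], A[l]) for k in range(K) for l in range(k + 1, K)])
    else:
        B = trial_psths(spikes_b)
        if len(B) != len(A):
            raise ValueError("models must have equal trial counts")
        K = len(A)
        vals = np.array([corr(A[k], B[l]) for k in range(K) for l in range(k, K)])
    return TrialCorrelation(float(np.nanmean(vals)), len(vals), vals)


# ---------------------------------------------------------------------------
# Spike-time reliability
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityResult:
    r_spike: np.ndarray         # per neuron, NaN where undefined
    sigma: float
    dt_signal: float
    n_trials: int

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.r_spike)


def spike_time_reliability(spikes: SpikeData, sigma: float = 5.0,
                           dt_signal: float = 0.5) -> ReliabilityResult:
    """Schreiber spike-time reliability: spike trains are convolved
    with a Gaussian kernel (width ``sigma`` ms on a ``dt_signal`` ms
    grid, truncated at 5σ) and r_spike(n) is the mean cosine similarity
    of the filtered signals across all trial pairs.  Trial pairs with
    an empty train are skipped; neurons with fewer than two nonempty
    trials are undefined (NaN)."""
    from scipy.ndimage import gaussian_filter1d

    K = spikes.n_trials
    if K < 2:
        raise ValueError("reliability needs at least 2 trials")
    nbins = int(np.ceil(spikes.duration / dt_signal))
    # per-trial, per-neuron spike-time lists
    per_trial: list[dict[int, np.ndarray]] = []
    for k in range(K):
        order = np.argsort(spikes.ids[k], kind="stable")
        ids_s, t_s = spikes.ids[k][order], spikes.times[k][order]
        uniq, starts = np.unique(ids_s, return_index=True)
        bounds = np.append(starts, len(ids_s))
        per_trial.append({int(u): t_s[bounds[i]:bounds[i + 1]]
                          for i, u in enumerate(uniq)})
    sigma_bins = sigma / dt_signal
    r = np.full(spikes.n_neurons, np.nan)
    for n in range(spikes.n_neurons):
        trains = [per_trial[k].get(n) for k in range(K)]
        live = [t for t in trains if t is not None and len(t)]
        if len(live) < 2:
            continue
        S = np.zeros((len(live), nbins))
        for row, t in enumerate(live):
            b = np.minimum((t / dt_signal).astype(np.int64), nbins - 1)
            np.add.at(S[row], b, 1.0)
        S = gaussian_filter1d(S, sigma_bins, axis=1, mode="constant", truncate=5.0)
        norms = np.linalg.norm(S, axis=1)
        G = (S @ S.T) / np.outer(norms, norms)
        iu = np.triu_indices(len(live), k=1)
        r[n] = float(G[iu].mean())
    return ReliabilityResult(r, sigma, dt_signal, K)


# ---------------------------------------------------------------------------
# Spatial clusters and exponential distance fit
# ---------------------------------------------------------------------------

@dataclass
class ExpFitResult:
    lam: float                  # decay length λ, µm
    offset: float
    stderr_lam: float
    stderr_offset: float


def spatial_cluster_correlations(neurons: pd.DataFrame, spikes: SpikeData,
                                 k: int = 100, dt: float = 20.0, seed: int = 0
                                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """k-means clustering of soma positions; correlation of the pooled
    cluster PSTHs for every cluster pair against the Euclidean distance
    of the cluster centers.

    Returns (distances, correlations, labels); clusters with a
    zero-variance PSTH are dropped from the pairing.
    """
    from sklearn.cluster import KMeans

    if k < 2:
        raise ValueError("need at least 2 clusters")
    xyz = neurons[["x_um", "y_um", "z_um"]].to_numpy()
    if k > len(xyz):
        raise ValueError("more clusters than neurons")
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2 ** 32))
    labels = km.fit_predict(xyz)
    X = _binned(spikes, dt)
    P = np.zeros((k, X.shape[1]))
    for c in range(k):
        P[c] = X[labels == c].sum(axis=0)
    ok = np.flatnonzero(P.std(axis=1) > 0)
    if len(ok) < 2:
        raise ValueError("fewer than 2 active clusters")
    R = np.corrcoef(P[ok])
    centers = km.cluster_centers_[ok]
    iu = np.triu_indices(len(ok), k=1)
    d = np.linalg.norm(centers[iu[0]] - centers[iu[1]], axis=1)
    return d, R[iu], labels


def fit_exponential(distances: np.ndarray, correlations: np.ndarray) -> ExpFitResult:
    """Unweighted least-squares fit of r(d) = exp(−d/λ) + c, with
    standard errors from the fit covariance.  Initial values: λ =
    median distance, c = minimum correlation."""
    from scipy.optimize import curve_fit

    d = np.asarray(distances, float)
    r = np.asarray(correlations, float)
    if len(d) < 3:
        raise ValueError("need at least 3 points")

    def model(x, lam, c):
        return np.exp(-x / lam) + c

    p0 = (float(np.median(d)), float(r.min()))
    popt, pcov = curve_fit(model, d, r, p0=p0, maxfev=10_000)
    if popt[0] <= 0:
        raise ValueError("degenerate fit: non-positive decay length")
    perr = np.sqrt(np.diag(pcov))
    return ExpFitResult(float(popt[0]), float(popt[1]), float(perr[0]), float(perr[1]))


# ---------------------------------------------------------------------------
# Simplex-position analyses
# ---------------------------------------------------------------------------

@dataclass
class SimplexCorrelationProfile:
    """Mean pair correlation by position inside maximal simplices.

    ``position_means[d]`` has one entry per consecutive pair position
    (0 = source pair, d−1 = sink pair) for maximal simplices of
    dimension d; ``sink_source_diff[d]`` = sink − source mean.
    """

    position_means: dict[int, np.ndarray]
    position_counts: dict[int, np.ndarray]
    sink_source_diff: dict[int, float]
    skipped_pairs: int

    def overall_mean(self, dim: int) -> float:
        m, c = self.position_means[dim], self.position_counts[dim]
        ok = c > 0
        return float(np.sum(m[ok] * c[ok]) / c[ok].sum()) if ok.any() else float("nan")


def simplex_position_correlations(R: CorrelationMatrix,
                                  maximal: list[tuple[int, ...]]
                                  ) -> SimplexCorrelationProfile:
    """Bin the correlation of consecutive neuron pairs (v_k, v_{k+1})
    of each maximal simplex by the pair's position k; pairs involving
    inactive neurons are skipped and counted."""
    sums: dict[int, np.ndarray] = {}
    counts: dict[int, np.ndarray] = {}
    skipped = 0
    for tup in maximal:
        d = len(tup) - 1
        if d < 1:
            continue
        if d not in sums:
            sums[d] = np.zeros(d)
            counts[d] = np.zeros(d, dtype=np.int64)
        for pos in range(d):
            v = R.value(tup[pos], tup[pos + 1])
            if np.isnan(v):
                skipped += 1
            else:
                sums[d][pos] += v
                counts[d][pos] += 1
    if not sums:
        raise ValueError("no maximal simplices of dimension >= 1")
    means = {d: np.where(counts[d] > 0, sums[d] / np.maximum(counts[d], 1), np.nan)
             for d in sums}
    diff = {d: float(means[d][-1] - means[d][0]) for d in means}
    return SimplexCorrelationProfile(means, counts, diff, skipped)


def correlation_by_participation(R: CorrelationMatrix,
                                 participation: ParticipationRecord,
                                 bin_edges: np.ndarray) -> pd.DataFrame:
    """Mean pair correlation of connections grouped by their simplex
    participation at the source and at the sink (2D binning).

    Returns a DataFrame (source_bin, sink_bin, mean_correlation,
    n_edges, populated); empty bins are flagged, not interpolated.
    """
    edges = participation.edges
    vals = np.array([R.value(u, v) for u, v in edges])
    ok = ~np.isnan(vals)
    src_bin = np.digitize(participation.n_source, bin_edges) - 1
    snk_bin = np.digitize(participation.n_sink, bin_edges) - 1
    nb = len(bin_edges) - 1
    rows = []
    for i in range(nb):
        for j in range(nb):
            m = ok & (src_bin == i) & (snk_bin == j)
            cnt = int(m.sum())
            rows.append((i, j, float(vals[m].mean()) if cnt else np.nan, cnt, cnt > 0))
    return pd.DataFrame(rows, columns=["source_bin", "sink_bin",
                                       "mean_correlation", "n_edges", "populated"])


def depth_profile(values: np.ndarray, neurons: pd.DataFrame,
                  bin_width: float = 50.0,
                  synapse_class: str | None = None) -> pd.DataFrame:
    """Bin a per-neuron quantity by soma depth: mean, SD, SEM and count
    per depth bin, optionally restricted to EXC or INH neurons."""
    df = neurons[["neuron_id", "y_um", "synapse_class"]].copy()
    df["value"] = np.asarray(values)[df["neuron_id"].to_numpy()]
    if synapse_class is not None:
        df = df[df["synapse_class"] == synapse_class]
    df = df.dropna(subset=["value"])
    df["bin"] = (df["y_um"] // bin_width).astype(int)
    g = df.groupby("bin")["value"]
    out = pd.DataFrame({"depth_um": (g.mean().index + 0.5) * bin_width,
                        "mean": g.mean(), "sd": g.std(ddof=0),
                        "n": g.size()})
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out.reset_index(drop=True)
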