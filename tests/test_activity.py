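import numpy as np
import pandas as pd
import pytest

import cloudcircuit as cc
from cloudcircuit.activity import (CorrelationMatrix, fit_exponential,
                                   population_trial_correlations,
                                   simplex_position_correlations,
                                   spike_time_reliability)
from cloudcircuit.simulate import SpikeData

from oracles import gaussian_filtered_overlap


def raster(trials, duration=100.0, n_neurons=4):
    """SpikeData from a list of per-trial {neuron: [times]} dicts."""
    times, ids = [], []
    for tr in trials:
        t_all, i_all = [], []
        for n, ts in tr.items():
            t_all.extend(ts)
            i_all.extend([n] * len(ts))
        order = np.argsort(t_all, kind="stable")
        times.append(np.asarray(t_all, dtype=float)[order])
        ids.append(np.asarray(i_all, dtype=np.int64)[order])
    return SpikeData(times, ids, duration, n_neurons)


class TestRatesAndEI:
    def test_rate_histogram_identity(self):
        sp = raster([{0: [5.0, 15.0], 1: [5.0]}, {0: [25.0]}])
        fr = cc.firing_rates(sp, dt=10.0)
        assert fr.counts.sum() == 4
        # 4 spikes, 4 neurons, 2 trials, 100 ms each -> 5 Hz
        assert fr.mean_rate_hz == pytest.approx(4 / 4 / 0.2)

    def test_ei_ratio(self, small_circuit):
        _, neurons, *_ = small_circuit
        exc = neurons.loc[neurons["synapse_class"] == "EXC", "neuron_id"].iloc[0]
        inh = neurons.loc[neurons["synapse_class"] == "INH", "neuron_id"].iloc[0]
        sp = raster([{int(exc): [1.0, 2.0, 3.0], int(inh): [1.0]},
                     {int(exc): [1.0]}], n_neurons=len(neurons))
        ei = cc.ei_spike_ratio(sp, neurons)
        assert ei.per_trial[0] == pytest.approx(3.0)
        assert np.isnan(ei.per_trial[1])        # no INH spikes in trial 2
        assert ei.pooled == pytest.approx(4.0)  # 4 EXC / 1 INH


class TestCorrelationMatrix:
    def test_identical_trains_correlate_to_1(self):
        sp = raster([{0: [5.0, 45.0], 1: [5.0, 45.0], 2: [25.0]}])
        R = cc.pairwise_correlation_matrix(sp, dt=10.0)
        assert R.value(0, 1) == pytest.approx(1.0)
        assert R.value(0, 0) == pytest.approx(1.0)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(0)
        trials = [{n: list(rng.uniform(0, 100, rng.integers(1, 8)))
                   for n in range(5)} for _ in range(3)]
        sp = raster(trials, n_neurons=5)
        R = cc.pairwise_correlation_matrix(sp, dt=10.0)
        from cloudcircuit.activity import _binned
        X = _binned(sp, 10.0)
        for i in range(5):
            for j in range(5):
                expect = np.corrcoef(X[i], X[j])[0, 1]
                assert R.value(i, j) == pytest.approx(expect, abs=1e-12)

    def test_inactive_neurons_excluded(self):
        sp = raster([{0: [5.0], 1: [15.0]}], n_neurons=4)
        R = cc.pairwise_correlation_matrix(sp, dt=10.0)
        assert 2 in R.excluded and 3 in R.excluded
        assert np.isnan(R.value(0, 2))


class TestTrialCorrelations:
    def test_pair_counts(self):
        def fake(K, seed=0):
            rng = np.random.default_rng(seed)
            return raster([{0: list(rng.uniform(0, 100, 5))} for _ in range(K)])
        assert population_trial_correlations(fake(30)).n_pairs == 435
        assert population_trial_correlations(fake(3)).n_pairs == 3
        # cross-model: 30 trials each -> K(K+1)/2 = 465 pairs
        res = population_trial_correlations(fake(30), spikes_b=fake(30, seed=1))
        assert res.n_pairs == 465

    def test_identical_trials_give_1(self):
        sp = raster([{0: [5.0, 25.0], 1: [45.0]}] * 4)
        res = population_trial_correlations(sp, dt=10.0)
        assert res.mean == pytest.approx(1.0)

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            population_trial_correlations(raster([{0: [1.0]}]))


class TestReliability:
    def test_two_single_spikes_closed_form(self):
        delta = 5.0
        sp = raster([{0: [40.0]}, {0: [40.0 + delta]}])
        res = spike_time_reliability(sp, sigma=5.0, dt_signal=0.5)
        assert res.r_spike[0] == pytest.approx(
            gaussian_filtered_overlap(0.0, delta, 5.0), abs=1e-3)

    def test_identical_trains_are_1(self):
        sp = raster([{0: [10.0, 30.0]}, {0: [10.0, 30.0]}])
        res = spike_time_reliability(sp)
        assert res.r_spike[0] == pytest.approx(1.0, abs=1e-9)

    def test_undefined_for_single_live_trial(self):
        sp = raster([{0: [10.0]}, {1: [10.0]}])
        res = spike_time_reliability(sp)
        assert np.isnan(res.r_spike[0]) and np.isnan(res.r_spike[1])
        assert not res.defined[0]

    def test_values_in_unit_interval(self, small_reference):
        params = cc.SimParams(duration=500.0, trials=3)
        sp = cc.simulate(small_reference, params, seed=1)
        res = spike_time_reliability(sp)
        vals = res.r_spike[res.defined]
        assert len(vals) > 0
        assert ((vals >= -1e-9) & (vals <= 1 + 1e-9)).all()


class TestExponentialFit:
    def test_recovers_parameters(self):
        rng = np.random.default_rng(4)
        lam, c = 150.0, 0.05
        d = rng.uniform(10, 600, 200)
        r = np.exp(-d / lam) + c + rng.normal(0, 0.005, 200)
        fit = fit_exponential(d, r)
        assert fit.lam == pytest.approx(lam, rel=0.1)
        assert fit.offset == pytest.approx(c, abs=0.02)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            fit_exponential([1.0, 2.0], [0.5, 0.4])


class TestSpatialClusters:
    def test_cluster_correlations(self, small_circuit, small_reference):
        _, neurons, *_ = small_circuit
        sp = cc.simulate(small_reference, cc.SimParams(duration=600.0, trials=2),
                         seed=9)
        d, r, labels = cc.spatial_cluster_correlations(neurons, sp, k=12, seed=0)
        assert len(d) == len(r)
        assert len(np.unique(labels)) == 12
        assert (d > 0).all()


class TestSimplexPositionProfile:
    def make_R(self, n, values):
        R = np.ones((n, n))
        for (i, j), v in values.items():
            R[i, j] = R[j, i] = v
        return CorrelationMatrix(np.arange(n), R, np.array([], dtype=int), 20.0)

    def test_positions_binned_correctly(self):
        # one 2-simplex (0,1,2): source pair (0,1), sink pair (1,2)
        R = self.make_R(3, {(0, 1): 0.1, (1, 2): 0.5, (0, 2): 0.9})
        prof = simplex_position_correlations(R, [(0, 1, 2)])
        assert prof.position_means[2][0] == pytest.approx(0.1)
        assert prof.position_means[2][1] == pytest.approx(0.5)
        assert prof.sink_source_diff[2] == pytest.approx(0.4)

    def test_inactive_pairs_skipped(self):
        R = CorrelationMatrix(np.array([0, 1]), np.ones((2, 2)),
                              np.array([2]), 20.0)
        prof = simplex_position_correlations(R, [(0, 1), (1, 2)])
        assert prof.skipped_pairs == 1
        assert prof.position_counts[1][0] == 1

    def test_empty_input_raises(self):
        R = self.make_R(2, {})
        with pytest.raises(ValueError):
            simplex_position_correlations(R, [(0,)])


class TestParticipationBinsAndDepth:
    def test_correlation_by_participation(self):
        R = TestSimplexPositionProfile().make_R(
            3, {(0, 1): 0.2, (1, 2): 0.6, (0, 2): 0.4})
        part = cc.connection_participation(
            np.array([[0, 1, 1], [0, 0, 1], [0, 0, 0]], dtype=bool), 2)
        df = cc.correlation_by_participation(R, part, np.array([0, 1, 10]))
        pop = df[df["populated"]]
        assert pop["n_edges"].sum() == 3
        # the source edge (0,1): n_source=1 -> bin 1; n_sink=0 -> bin 0
        row = df[(df["source_bin"] == 1) & (df["sink_bin"] == 0)].iloc[0]
        assert row["mean_correlation"] == pytest.approx(0.2)

    def test_depth_profile(self, small_circuit):
        _, neurons, *_ = small_circuit
        vals = neurons["y_um"].to_numpy() * 2.0
        prof = cc.depth_profile(vals, neurons, bin_width=100.0)
        assert (prof["n"] > 0).all()
        # mean of 2*y within a depth bin is close to 2*bin center
        mid = prof.iloc[2]
        assert mid["mean"] == pytest.approx(2 * mid["depth_um"], rel=0.15)
        assert prof["sem"].iloc[0] == pytest.approx(
            prof["sd"].iloc[0] / np.sqrt(prof["n"].iloc[0]))
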