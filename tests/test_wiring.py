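import numpy as np
import pandas as pd
import pytest

import cloudcircuit as cc
from cloudcircuit.circuit import CloudComponent, render_density
from cloudcircuit.wiring import (Connectome, convolve_clouds, mean_type_density,
                                 sample_without_replacement,
                                 sequential_sample_without_replacement,
                                 transfer_and_normalize)

from conftest import make_circuit
from hypothesis import given, settings
from hypothesis import strategies as st


class TestFields:
    def test_convolution_mass_is_product_of_masses(self):
        axon = render_density([CloudComponent((0, -30), (25, 40), 1.5)], 2.0)
        dend = render_density([CloudComponent((5, 10), (30, 20), 0.7)], 2.0)
        F = convolve_clouds(dend, axon)
        assert F.mass == pytest.approx(axon.mass * dend.mass, rel=1e-9)

    def test_mean_type_density(self):
        g1 = render_density([CloudComponent((0, 0), (20, 20), 1.0)], 2.0)
        g2 = render_density([CloudComponent((0, 0), (20, 20), 3.0)], 2.0)
        m = mean_type_density([g1, g2])
        assert np.allclose(m.values, (g1.values + g2.values) / 2)

    def test_mismatched_grids_rejected(self):
        g1 = render_density([CloudComponent((0, 0), (20, 20))], 2.0)
        g2 = render_density([CloudComponent((0, 0), (30, 30))], 2.0)
        with pytest.raises(ValueError):
            mean_type_density([g1, g2])


class TestTransfer:
    def test_square_transfer_and_normalization(self):
        O = np.array([[1.0, 2.0], [3.0, 0.0]])
        blk = transfer_and_normalize(O)
        assert np.allclose(blk.O_transferred, O ** 2)
        assert blk.P.sum() == pytest.approx(1.0)
        assert blk.P[1, 0] == pytest.approx(9 / 14)

    def test_negative_rejected_and_empty_flag(self):
        with pytest.raises(ValueError):
            transfer_and_normalize(np.array([[-1.0]]))
        assert transfer_and_normalize(np.zeros((2, 2))).empty


class TestSamplers:
    def test_distinct_sorted_indices(self):
        w = np.array([1.0, 2.0, 0.0, 4.0, 0.5])
        for seed in range(20):
            idx = sample_without_replacement(w, 3, seed)
            assert len(set(idx)) == 3
            assert (np.sort(idx) == idx).all()
            assert 2 not in idx  # zero weight never picked

    def test_infeasible_raises(self):
        w = np.array([1.0, 0.0, 2.0])
        with pytest.raises(ValueError, match="infeasible"):
            sample_without_replacement(w, 3, 0)
        with pytest.raises(ValueError, match="infeasible"):
            sequential_sample_without_replacement(w, 3, 0)

    def test_k_equals_support_returns_support(self):
        w = np.array([0.0, 5.0, 1.0, 0.0, 2.0])
        assert list(sample_without_replacement(w, 3, 7)) == [1, 2, 4]

    def test_zero_draws(self):
        assert len(sample_without_replacement(np.ones(4), 0, 0)) == 0

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_sequential_sampler_valid_output(self, seed):
        w = np.array([0.5, 1.5, 0.0, 3.0])
        idx = sequential_sample_without_replacement(w, 2, seed)
        assert len(set(idx)) == 2 and 2 not in idx


class TestCloudWiring:
    def test_macroconnectome_conserved_exactly(self, small_circuit, small_cloud):
        *_, ref = small_circuit
        assert ref.pair_count_dict() == small_cloud.pair_count_dict()

    def test_zero_jitter_identical_selection_probabilities(self):
        # at eta = 0 the instance overlaps reduce to the type fields, so
        # reference and cloud draw from the same block distributions
        import cloudcircuit.wiring as wiring
        from cloudcircuit.circuit import _pair_offsets, _lookup_field

        spec, neurons, morphs, targets, ref = make_circuit(
            n_neurons=150, jitter=0.0, seed=2, mean_degree=15)
        fields = wiring._type_fields(spec)
        xyz = neurons[["x_um", "y_um", "z_um"]].to_numpy()
        for (mi, mj), F in fields.items():
            pre = np.flatnonzero((neurons["m_type"] == mi).to_numpy())
            post = np.flatnonzero((neurons["m_type"] == mj).to_numpy())
            r, dy = _pair_offsets(xyz[pre], xyz[post])
            O_cloud = _lookup_field(F.values, F.bin, F.lat0, F.depth0, r, dy)
            xyzj = xyz + morphs.displacement
            rj, dyj = _pair_offsets(xyzj[pre], xyzj[post])
            O_ref = _lookup_field(F.values, F.bin, F.lat0, F.depth0, rj, dyj)
            O_ref = O_ref * np.outer(morphs.scale[pre], morphs.scale[post])
            assert np.array_equal(O_cloud, O_ref)

    def test_jitter_increases_degree_heterogeneity(self):
        # the central qualitative effect: morphological diversity makes
        # in/out-degree distributions heavier-tailed than the cloud's
        wins = 0
        for seed in range(5):
            spec, neurons, morphs, targets, ref = make_circuit(
                n_neurons=300, jitter=25.0, seed=seed, mean_degree=25)
            cloud = cc.build_cloud_connectome(ref, spec, seed=seed)
            s_ref = cc.degree_summary(ref)
            s_cld = cc.degree_summary(cloud)
            wins += (s_ref.sigma_in > s_cld.sigma_in
                     and s_ref.sigma_out > s_cld.sigma_out)
        assert wins >= 4


@pytest.fixture(scope="module")
def transplanted(small_reference, small_cloud):
    return cc.transplant(small_cloud, small_reference, seed=3)


class TestTransplant:
    def test_loss_accounting_identity(self, transplanted):
        _, loss = transplanted
        t = loss.table
        assert (t["required"] == t["placed"] + t["lost"]).all()
        assert (t["duplicated"] >= 0).all()

    def test_placed_matches_cloud_demand(self, transplanted, small_cloud):
        hybrid, loss = transplanted
        # every placed edge corresponds to a cloud edge (EXC part)
        ann_c = small_cloud.mtypes_of_edges()
        exc_cloud = ann_c[ann_c["pre_class"] == "EXC"]
        assert loss.table["required"].sum() == len(exc_cloud)
        ann_h = hybrid.mtypes_of_edges()
        exc_h = ann_h[ann_h["pre_class"] == "EXC"]
        assert len(exc_h) == loss.table["placed"].sum()

    def test_inhibitory_subgraph_unchanged(self, transplanted, small_reference):
        hybrid, _ = transplanted
        def inh(conn):
            ann = conn.mtypes_of_edges()
            sub = ann[ann["pre_class"] == "INH"]
            return sub.sort_values(["pre_id", "post_id"])[
                ["pre_id", "post_id", "synapse_count", "path_length_um"]
            ].reset_index(drop=True)
        pd.testing.assert_frame_equal(inh(hybrid), inh(small_reference))

    def test_attributes_come_from_reference_slots(self, transplanted,
                                                  small_reference):
        hybrid, _ = transplanted
        ann_h = hybrid.mtypes_of_edges()
        ann_r = small_reference.mtypes_of_edges()
        for post_id, g in ann_h[ann_h["pre_class"] == "EXC"].groupby("post_id"):
            ref_g = ann_r[(ann_r["post_id"] == post_id)
                          & (ann_r["pre_class"] == "EXC")]
            ref_pairs = set(zip(ref_g["pre_mtype"],
                                np.round(ref_g["path_length_um"], 9)))
            for _, row in g.iterrows():
                assert (row["pre_mtype"],
                        round(row["path_length_um"], 9)) in ref_pairs


class TestControls:
    def test_matched_removal_exact(self, small_reference, small_cloud):
        _, loss = cc.transplant(small_cloud, small_reference, seed=3)
        control = cc.matched_removal(small_reference, loss, seed=4)
        before = small_reference.pair_count_dict()
        after = control.pair_count_dict()
        lost = loss.lost_dict()
        for key, n in before.items():
            assert after.get(key, 0) == n - lost.get(key, 0)

    def test_shuffle_preserves_group_multisets(self, small_reference):
        shuffled = cc.shuffle_path_length(small_reference, seed=8)
        ann0 = small_reference.mtypes_of_edges()
        ann1 = shuffled.mtypes_of_edges()
        # per (post, pre m-type) group, the path-length multiset is intact
        for key, g0 in ann0.groupby(["post_id", "pre_mtype"]):
            g1 = ann1.groupby(["post_id", "pre_mtype"]).get_group(key)
            assert sorted(np.round(g0["path_length_um"], 9)) == \
                sorted(np.round(g1["path_length_um"], 9))
        # everything else untouched
        assert shuffled.edges[["pre_id", "post_id", "synapse_count"]].equals(
            small_reference.edges[["pre_id", "post_id", "synapse_count"]])
        # inhibitory edges bitwise identical
        inh0 = ann0[ann0["pre_class"] == "INH"]["path_length_um"].to_numpy()
        inh1 = ann1[ann1["pre_class"] == "INH"]["path_length_um"].to_numpy()
        assert np.array_equal(inh0, inh1)


class TestConnectomeContainer:
    def test_rejects_self_edges_and_duplicates(self, small_circuit):
        spec, neurons, *_ = small_circuit
        with pytest.raises(ValueError):
            Connectome(pd.DataFrame({"pre_id": [1], "post_id": [1]}), neurons)
        with pytest.raises(ValueError):
            Connectome(pd.DataFrame({"pre_id": [1, 1], "post_id": [2, 2]}),
                       neurons)

    def test_adjacency_roundtrip(self, small_reference):
        A = small_reference.adjacency()
        assert A.sum() == small_reference.n_edges
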