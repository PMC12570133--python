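"""Cluster characterization: populations, consensus/difference graphs,
representative selection, structural observables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rin_states import (ClusterLabels, bin_edge_weights, cluster_populations,
                        consensus_graph, contact_probability_series,
                        difference_graph, interface_score, mean_fingerprint,
                        radius_of_gyration, select_centroid,
                        select_evenly_spaced, select_exemplars)
from rin_states.errors import DimensionError
from rin_states.fingerprints import FingerprintMatrix
from rin_states.landscape import LandscapeEmbedding
from rin_states.rin import ContactGraph
from rin_states.states import ConsensusGraph
from rin_states.synthetic import generate_random_connected_graph


def _labels(seq):
    return ClusterLabels(labels=np.asarray(seq, dtype=int))


def _fp(values):
    values = np.asarray(values, dtype=float)
    return FingerprintMatrix(values=values,
                             residue_labels=tuple(("R", i + 1, "A")
                                                  for i in range(values.shape[1])),
                             normalized=True, normalization_factor=1.0)


class TestPopulations:
    def test_fractions_with_noise(self):
        pops = cluster_populations(_labels([0, 0, 1, -1]))
        assert pops == {0: 0.5, 1: 0.25, -1: 0.25}

    def test_single_cluster(self):
        assert cluster_populations(_labels([0, 0, 0]))[0] == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        pops = cluster_populations(_labels(rng.integers(-1, 4, size=500)))
        assert sum(pops.values()) == pytest.approx(1.0, abs=1e-15)


class TestMeanFingerprint:
    def test_columnwise_mean(self):
        m = _fp([[0.2, 0.4], [0.4, 0.6], [0.9, 0.9]])
        np.testing.assert_allclose(
            mean_fingerprint(m, _labels([0, 0, 1]), 0), [0.3, 0.5])

    def test_single_member_is_identity(self):
        m = _fp([[0.1, 0.2], [0.7, 0.8]])
        np.testing.assert_array_equal(
            mean_fingerprint(m, _labels([1, 0]), 0), [0.7, 0.8])

    def test_bounded_by_member_extremes(self):
        rng = np.random.default_rng(1)
        m = _fp(rng.random((50, 8)))
        lab = _labels(rng.integers(0, 3, size=50))
        for c in range(3):
            mf = mean_fingerprint(m, lab, c)
            rows = m.values[lab.labels == c]
            assert (mf >= rows.min(axis=0) - 1e-15).all()
            assert (mf <= rows.max(axis=0) + 1e-15).all()

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            mean_fingerprint(_fp([[0.1]]), _labels([0]), 5)


def _random_graphs(n_graphs, n_nodes, p, seed):
    return [generate_random_connected_graph(n_nodes, p, seed + k)
            for k in range(n_graphs)]


class TestConsensusGraph:
    def test_identical_members_give_binary_weights(self):
        g = generate_random_connected_graph(10, 0.3, 0)
        cg = consensus_graph([g] * 4, _labels([0] * 4), 0)
        np.testing.assert_array_equal(cg.weights, g.adjacency.astype(float))

    def test_three_of_four(self):
        gs = _random_graphs(4, 8, 0.2, 5)
        # force a specific edge present in exactly 3 members
        for g in gs[:3]:
            g.adjacency[0, 5] = g.adjacency[5, 0] = True
        gs[3].adjacency[0, 5] = gs[3].adjacency[5, 0] = False
        cg = consensus_graph(gs, _labels([0] * 4), 0)
        assert cg.weights[0, 5] == 0.75

    def test_matches_per_edge_counting_oracle(self):
        gs = _random_graphs(50, 12, 0.25, 17)
        lab = _labels([0] * 50)
        cg = consensus_graph(gs, lab, 0)
        n = 12
        for i in range(n):
            for j in range(n):
                count = sum(g.adjacency[i, j] for g in gs)
                assert cg.weights[i, j] == count / 50

    def test_backbone_weight_is_one(self, small_graphs):
        lab = _labels([0] * len(small_graphs))
        cg = consensus_graph(small_graphs, lab, 0)
        for i in range(cg.n_nodes - 1):
            assert cg.weights[i, i + 1] == 1.0

    def test_consensus_equals_mean_contact_indicator(self):
        gs = _random_graphs(30, 10, 0.3, 23)
        lab = _labels([0] * 30)
        cg = consensus_graph(gs, lab, 0)
        for pair in [(0, 7), (2, 5), (3, 9)]:
            series = contact_probability_series(gs, pair)
            assert series.values.mean() == cg.weights[pair]


class TestBinEdgeWeights:
    @pytest.mark.parametrize("w,expected", [
        (0.30, "low"), (0.60, "mid"), (0.91, "high"),
        (0.50, "mid"), (0.75, "high"), (1.0, "high"), (0.25, "low"),
    ])
    def test_interval_membership(self, w, expected):
        weights = np.zeros((3, 3))
        weights[0, 1] = weights[1, 0] = w
        cg = ConsensusGraph(weights=weights, cluster_id=0, n_members=10)
        assert bin_edge_weights(cg)[(0, 1)] == expected

    def test_below_quarter_not_displayed(self):
        weights = np.zeros((3, 3))
        weights[0, 1] = weights[1, 0] = 0.20
        cg = ConsensusGraph(weights=weights, cluster_id=0, n_members=10)
        assert (0, 1) not in bin_edge_weights(cg)


class TestDifferenceGraph:
    def _consensus_pair(self):
        gs_a = _random_graphs(20, 9, 0.3, 31)
        gs_b = _random_graphs(20, 9, 0.5, 77)
        lab = _labels([0] * 20)
        return (consensus_graph(gs_a, lab, 0), consensus_graph(gs_b, lab, 0))

    def test_self_difference_is_zero(self):
        a, _ = self._consensus_pair()
        np.testing.assert_array_equal(difference_graph(a, a).weights, 0.0)

    def test_antisymmetric(self):
        a, b = self._consensus_pair()
        np.testing.assert_array_equal(difference_graph(a, b).weights,
                                      -difference_graph(b, a).weights)

    def test_signed_magnitude(self):
        wa = np.zeros((4, 4)); wa[1, 2] = wa[2, 1] = 0.9
        wb = np.zeros((4, 4)); wb[1, 2] = wb[2, 1] = 0.1
        d = difference_graph(ConsensusGraph(wa, 0, 5), ConsensusGraph(wb, 1, 5))
        assert d.weights[1, 2] == pytest.approx(0.8)
        assert abs(d.weights[1, 2]) > d.display_threshold

    def test_dimension_mismatch(self):
        a = ConsensusGraph(np.zeros((3, 3)), 0, 1)
        b = ConsensusGraph(np.zeros((4, 4)), 1, 1)
        with pytest.raises(DimensionError):
            difference_graph(a, b)


class TestContactProbabilitySeries:
    def test_constant_when_always_present(self):
        gs = [generate_random_connected_graph(6, 1.0, s) for s in range(5)]
        series = contact_probability_series(gs, (0, 4))
        np.testing.assert_array_equal(series.values, 1.0)

    def test_planted_contact_state_specific(self, small_ensemble, small_graphs,
                                            small_spec):
        _, planted = small_ensemble
        for s_idx, state in enumerate(small_spec.states):
            for pair in sorted(state.interface_pairs):
                series = contact_probability_series(small_graphs, pair)
                inside = series.values[planted == s_idx]
                outside = series.values[planted != s_idx]
                assert inside.mean() == 1.0
                assert outside.mean() == 0.0

    def test_out_of_range_rejected(self, small_graphs):
        with pytest.raises(ValueError):
            contact_probability_series(small_graphs, (0, 999))


class TestRadiusOfGyration:
    def test_two_equal_masses(self):
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        assert radius_of_gyration(frame, [0, 1]) == pytest.approx(0.5)

    def test_coincident_atoms(self):
        assert radius_of_gyration(np.zeros((5, 3)), range(5)) == 0.0

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(4)
        frame = rng.random((50, 3))
        masses = rng.uniform(1, 16, 50)
        com = (masses[:, None] * frame).sum(0) / masses.sum()
        expected = np.sqrt((masses * ((frame - com) ** 2).sum(1)).sum() / masses.sum())
        got = radius_of_gyration(frame, range(50), masses)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_matches_mdtraj(self):
        import mdtraj as md

        top = md.Topology()
        chain = top.add_chain()
        rng = np.random.default_rng(8)
        for i in range(10):
            res = top.add_residue("ALA", chain, resSeq=i + 1)
            top.add_atom("CA", md.element.carbon, res)
        xyz = rng.random((1, 10, 3)).astype(np.float32)
        traj = md.Trajectory(xyz=xyz, topology=top)
        expected = md.compute_rg(traj)[0]
        got = radius_of_gyration(xyz[0].astype(float), range(10),
                                 [12.011] * 10)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((3, 3)), [])


class TestInterfaceScore:
    def _graph_with_cross_contacts(self, red_cd, blue_cd, n=20):
        adj = np.zeros((n, n), dtype=bool)
        for i, j in red_cd + blue_cd:
            adj[i, j] = adj[j, i] = True
        return ContactGraph(adjacency=adj, cutoff=0.45)

    def test_signed_count(self):
        # split = 4: residues 0..4 are "red", 5..9 "blue"; CD = 10..19
        g = self._graph_with_cross_contacts(
            red_cd=[(0, 12), (2, 15), (4, 19)], blue_cd=[(7, 13)])
        assert interface_score(g, split=4, domain_nd=(0, 9), domain_cd=(10, 19)) == 2

    def test_no_cross_contacts_zero(self):
        g = self._graph_with_cross_contacts([], [])
        assert interface_score(g, 4, (0, 9), (10, 19)) == 0

    def test_balanced_sections_cancel(self):
        g = self._graph_with_cross_contacts(
            red_cd=[(1, 11), (3, 14)], blue_cd=[(6, 11), (8, 17)])
        assert interface_score(g, 4, (0, 9), (10, 19)) == 0

    def test_overlapping_domains_rejected(self):
        g = self._graph_with_cross_contacts([], [])
        with pytest.raises(ValueError):
            interface_score(g, 4, (0, 12), (10, 19))


class TestSelectEvenlySpaced:
    def test_stated_index_formula_m100_n10(self):
        members = list(range(1000, 1100))
        picked = select_evenly_spaced(members, 10)
        assert picked == [1000 + i for i in (0, 11, 22, 33, 44, 55, 66, 77, 88, 99)]

    def test_short_list_returned_whole(self):
        assert select_evenly_spaced([1, 2, 3, 4, 5], 10) == [1, 2, 3, 4, 5]

    def test_n_one_gives_first(self):
        assert select_evenly_spaced(list(range(50)), 1) == [0]

    @given(m=st.integers(1, 200), n=st.integers(1, 20))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_endpoints_and_count(self, m, n):
        members = list(range(m))
        picked = select_evenly_spaced(members, n)
        assert len(picked) == min(m, n)
        assert picked[0] == 0
        if m >= n > 1:
            assert picked[-1] == m - 1
        assert picked == sorted(picked)


class TestSelectExemplars:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.concatenate([rng.normal(0, 0.3, (80, 2)),
                              rng.normal(5, 0.3, (60, 2))])
        emb = LandscapeEmbedding(coords=pts, method="external")
        lab = _labels([0] * 80 + [1] * 60)
        return emb, lab

    def test_exemplars_belong_to_cluster(self):
        emb, lab = self._setup()
        for c in (0, 1):
            ex = select_exemplars(lab, emb, c, n=10)
            assert len(ex) == 10
            assert all(lab.labels[i] == c for i in ex)

    def test_backend_set_smaller_than_n_kept_whole(self):
        emb, lab = self._setup()
        ex = select_exemplars(lab, emb, 0, n=10, exemplar_indices=[0, 3, 5, 9, 11, 20, 33])
        assert ex == [0, 3, 5, 9, 11, 20, 33]

    def test_backend_set_reduced_by_even_spacing(self):
        emb, lab = self._setup()
        ex = select_exemplars(lab, emb, 0, n=10, exemplar_indices=list(range(80)))
        assert ex == select_evenly_spaced(list(range(80)), 10)


class TestSelectCentroid:
    def test_single_exemplar(self):
        m = _fp([[0.5, 0.5]])
        assert select_centroid([0], m) == 0

    def test_collinear_median(self):
        m = _fp([[0.0, 0.0], [0.5, 0.5], [1.0, 1.0]])
        assert select_centroid([0, 1, 2], m) == 1

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(6)
        m = _fp(rng.random((40, 7)))
        ex = sorted(rng.choice(40, size=20, replace=False).tolist())
        pts = m.values[ex]
        sums = [sum(np.linalg.norm(pts[a] - pts[b]) for b in range(20))
                for a in range(20)]
        expected = ex[int(np.argmin(sums))]
        assert select_centroid(ex, m) == expected

    def test_tie_broken_by_lowest_frame_index(self):
        m = _fp([[0.0, 0.0], [1.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        # frames 0..3 form two coincident pairs: all sums equal
        assert select_centroid([2, 1, 0, 3], m) == 0
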