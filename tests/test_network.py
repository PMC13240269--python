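"""Graph metrics against brute-force and networkx oracles; feature table."""

import numpy as np
import pandas as pd
import pytest

from netstab import (
    ConnectivityMatrix,
    DataError,
    GraphDisconnectedError,
    WeightedGraph,
    build_feature_table,
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    strength_centrality,
    to_graph,
)
from netstab.network import FeatureTable
from netstab.synthetic import DEFAULT_CHANNELS, default_channel_roles


def _graph(w):
    w = np.asarray(w, dtype=float)
    return WeightedGraph([f"n{i}" for i in range(len(w))], w)


def _random_graph(rng, n, density=0.7):
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(len(iu)) < density
    w[iu[keep], ju[keep]] = rng.uniform(0.05, 1.0, keep.sum())
    return _graph(w + w.T)


def _floyd_warshall(w):
    n = len(w)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


TRIANGLE = [[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]
STAR = [[0, 1, 1, 1], [1, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0, 0]]


class TestToGraph:
    def test_uniform_triangle(self):
        cm = ConnectivityMatrix("s", "theta", "plv",
                                np.array([[1, .5, .5], [.5, 1, .5], [.5, .5, 1.]]))
        g = to_graph(cm)
        np.testing.assert_allclose(g.weights, TRIANGLE)

    def test_proportional_threshold_edge_count(self, rng):
        w = rng.uniform(0.1, 0.9, size=(4, 4))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        g = to_graph(w, threshold_p=0.5)
        assert (np.triu(g.weights, 1) > 0).sum() == 3

    def test_tied_weights_resolved_by_edge_order(self):
        w = np.zeros((4, 4))
        iu, ju = np.triu_indices(4, 1)
        w[iu, ju] = [0.5, 0.5, 0.5, 0.5, 0.5, 0.5]
        w = w + w.T
        g1 = to_graph(w, threshold_p=0.5)
        g2 = to_graph(w, threshold_p=0.5)
        np.testing.assert_array_equal(g1.weights, g2.weights)
        # earliest upper-triangle edges retained: (0,1), (0,2), (0,3)
        assert g1.weights[0, 1] > 0 and g1.weights[0, 2] > 0 and g1.weights[0, 3] > 0
        assert g1.weights[1, 2] == 0


class TestNodeMetrics:
    def test_strength_on_toy_graphs(self):
        np.testing.assert_allclose(strength_centrality(_graph(TRIANGLE)), 1.0)
        np.testing.assert_allclose(strength_centrality(_graph(STAR)), [3, 1, 1, 1])

    def test_strength_equals_row_sums(self, rng):
        g = _random_graph(rng, 6)
        expected = [sum(g.weights[i, j] for j in range(6)) for i in range(6)]
        np.testing.assert_allclose(strength_centrality(g), expected, atol=1e-12)

    def test_clustering_binary_toys(self):
        tri = np.array(TRIANGLE) * 2.0  # weights 1.0 after the triangle scaling
        np.testing.assert_allclose(clustering_coefficient(_graph(tri)), 1.0)
        np.testing.assert_allclose(clustering_coefficient(_graph(STAR)), 0.0)

    def test_clustering_matches_triple_enumeration(self, rng):
        g = _random_graph(rng, 5)
        w = g.weights
        w_hat = np.cbrt(w / w.max())
        expected = np.zeros(5)
        for i in range(5):
            k = (w[i] > 0).sum()
            if k < 2:
                continue
            total = 0.0
            for j in range(5):
                for h in range(5):
                    if j != i and h != i and j != h:
                        total += w_hat[i, j] * w_hat[i, h] * w_hat[j, h]
            expected[i] = total / (k * (k - 1))
        np.testing.assert_allclose(clustering_coefficient(g), expected, atol=1e-12)


class TestGlobalMetrics:
    def test_complete_graph_efficiency_is_one(self):
        w = 1.0 - np.eye(5)
        assert global_efficiency(_graph(w)) == pytest.approx(1.0)

    def test_three_node_path(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        assert global_efficiency(_graph(w)) == pytest.approx(5 / 6)

    def test_isolated_nodes_give_zero(self):
        assert global_efficiency(_graph(np.zeros((2, 2)))) == 0.0

    def test_four_cycle_path_length(self):
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            w[i, j] = w[j, i] = 1.0
        assert characteristic_path_length(_graph(w)) == pytest.approx(4 / 3)

    def test_complete_graph_path_length_is_one(self):
        assert characteristic_path_length(_graph(1.0 - np.eye(4))) == pytest.approx(1.0)

    def test_single_edge_inverse_weight(self):
        w = np.array([[0, 0.5], [0.5, 0]])
        assert characteristic_path_length(_graph(w)) == pytest.approx(2.0)

    def test_disconnected_raises_with_fallback(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 0.5
        g = _graph(w)
        with pytest.raises(GraphDisconnectedError):
            characteristic_path_length(g)
        with pytest.warns(RuntimeWarning, match="largest component"):
            val = characteristic_path_length(g, on_disconnected="largest")
        assert val == pytest.approx(1.0)  # ties resolved to the first component

    def test_matches_floyd_warshall_oracle(self, rng):
        """Randomised check on all graphs up to 8 nodes vs brute force."""
        for n in range(2, 9):
            for _ in range(6):
                g = _random_graph(rng, n, density=rng.uniform(0.3, 1.0))
                d = _floyd_warshall(g.weights)
                off = ~np.eye(n, dtype=bool)
                inv = np.where(np.isfinite(d[off]), 1.0 / d[off], 0.0)
                assert global_efficiency(g) == pytest.approx(inv.mean(), abs=1e-10)
                if np.isfinite(d[off]).all():
                    assert characteristic_path_length(g) == pytest.approx(
                        d[off].mean(), abs=1e-10
                    )

    def test_matches_networkx(self, rng):
        import networkx as nx

        g = _random_graph(rng, 7)
        G = nx.Graph()
        G.add_nodes_from(range(7))
        for i in range(7):
            for j in range(i + 1, 7):
                if g.weights[i, j] > 0:
                    G.add_edge(i, j, dist=1.0 / g.weights[i, j])
        lengths = dict(nx.all_pairs_dijkstra_path_length(G, weight="dist"))
        inv_sum = sum(
            1.0 / lengths[i][j]
            for i in range(7) for j in range(7)
            if i != j and j in lengths[i]
        )
        assert global_efficiency(g) == pytest.approx(inv_sum / 42, abs=1e-10)

    def test_efficiency_monotone_under_edge_addition(self, rng):
        g = _random_graph(rng, 6, density=0.4)
        before = global_efficiency(g)
        w = g.weights.copy()
        iu, ju = np.triu_indices(6, 1)
        empty = [(i, j) for i, j in zip(iu, ju) if w[i, j] == 0]
        if not empty:
            pytest.skip("random graph came out complete")
        i, j = empty[0]
        w[i, j] = w[j, i] = 0.9
        assert global_efficiency(_graph(w)) >= before - 1e-12


def _toy_connectivity(values, subjects=("s1", "s2")):
    out = {}
    for k, sid in enumerate(subjects):
        mats = {}
        for measure in ("plv", "coh"):
            for band in ("delta", "theta", "alpha", "beta"):
                mats[(measure, band)] = ConnectivityMatrix(
                    sid, band, measure, values
                )
        out[sid] = mats
    return out


class TestFeatureTable:
    def test_single_channel_regions_pass_through_entry(self):
        vals = np.array([[1.0, 0.37], [0.37, 1.0]])
        conn = _toy_connectivity(vals)
        table = build_feature_table(
            conn, {"s1": "P", "s2": "HC"}, ["F3", "P3"],
            {"F3": "frontal", "P3": "parietal"},
        )
        assert table.features.loc[0, "plv_theta_frontal-parietal"] == pytest.approx(0.37)
        # single-channel regions emit no within-region pair columns
        assert "plv_theta_frontal-frontal" not in table.features.columns

    def test_default_montage_feature_count(self, rng):
        w = rng.uniform(0.1, 0.9, size=(16, 16))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        conn = _toy_connectivity(w)
        table = build_feature_table(
            conn, {"s1": "P", "s2": "HC"}, list(DEFAULT_CHANNELS),
            default_channel_roles(DEFAULT_CHANNELS),
        )
        # 5 regions -> 15 unordered region pairs, + 4 summary metrics,
        # x 4 bands x 2 measures
        assert table.features.shape[1] == (15 + 4) * 4 * 2

    def test_subject_order_only_permutes_rows(self, rng):
        w = rng.uniform(0.1, 0.9, size=(4, 4))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        labels = {"s1": "P", "s2": "HC"}
        chans = ["F3", "F4", "P3", "P4"]
        roles = {c: ("frontal" if c.startswith("F") else "parietal") for c in chans}
        t1 = build_feature_table(_toy_connectivity(w, ("s1", "s2")), labels, chans, roles)
        t2 = build_feature_table(_toy_connectivity(w, ("s2", "s1")), labels, chans, roles)
        a = t1.features.set_index(t1.subjects)
        b = t2.features.set_index(t2.subjects)
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_channel_permutation_within_region_invariant(self, rng):
        w = rng.uniform(0.1, 0.9, size=(4, 4))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        chans = ["F3", "F4", "P3", "P4"]
        roles = {c: ("frontal" if c.startswith("F") else "parietal") for c in chans}
        perm = [1, 0, 3, 2]  # swap channels inside each region
        wp = w[np.ix_(perm, perm)]
        chans_p = [chans[i] for i in perm]
        t1 = build_feature_table(_toy_connectivity(w), {"s1": "P", "s2": "HC"},
                                 chans, roles)
        t2 = build_feature_table(_toy_connectivity(wp), {"s1": "P", "s2": "HC"},
                                 chans_p, roles)
        pd.testing.assert_frame_equal(t1.features, t2.features)

    def test_missing_matrix_rejected(self):
        conn = _toy_connectivity(np.array([[1.0, 0.3], [0.3, 1.0]]))
        del conn["s1"][("plv", "theta")]
        with pytest.raises(DataError):
            build_feature_table(conn, {"s1": "P", "s2": "HC"}, ["F3", "P3"],
                                {"F3": "frontal", "P3": "parietal"})

    def test_tsv_round_trip(self, toy_table, tmp_path):
        path = tmp_path / "features.tsv"
        toy_table.to_tsv(path)
        back = FeatureTable.from_tsv(path)
        pd.testing.assert_frame_equal(back.features, toy_table.features)
        assert (back.labels == toy_table.labels).all()
        assert (back.subjects == toy_table.subjects).all()
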