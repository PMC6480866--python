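import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from oitnet.tda import (
    SimilarityMatrix,
    choose_k,
    louvain_partition,
    mutual_knn_graph,
    prioritize_features,
    set_distance,
    spearman_adjacency,
)
from tests.conftest import planted_two_block_table


def sim_from(matrix, names, n_samples=100):
    rho = pd.DataFrame(matrix, index=names, columns=names)
    return SimilarityMatrix(rho=rho, n_samples=n_samples)


class TestChooseK:
    @pytest.mark.parametrize(
        "n,expected", [(91, 5), (67, 5), (2, 1), (200, 6), (3, 2)]
    )
    def test_natural_log_ceiling(self, n, expected):
        assert choose_k(n) == expected
        assert choose_k(n) == min(max(1, math.ceil(math.log(n))), n - 1)

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            choose_k(1)


class TestSpearmanAdjacency:
    def test_monotone_pairs_attain_plus_minus_one(self):
        df = pd.DataFrame({"up": [1.0, 2, 3, 4], "exp_up": np.exp([1.0, 2, 3, 4]),
                           "down": [9.0, 7, 5, 1]})
        sim = spearman_adjacency(df)
        assert sim.rho.loc["up", "exp_up"] == pytest.approx(1.0)
        assert sim.rho.loc["up", "down"] == pytest.approx(-1.0)

    def test_tied_values_match_average_rank_formula(self):
        # hand-checkable toy with ties (n=6)
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0]
        y = [10.0, 30.0, 20.0, 20.0, 50.0, 40.0]
        sim = spearman_adjacency(pd.DataFrame({"x": x, "y": y}))
        rx, ry = rankdata(x), rankdata(y)  # average ranks
        expected = np.corrcoef(rx, ry)[0, 1]
        assert sim.rho.loc["x", "y"] == pytest.approx(expected, abs=1e-12)

    def test_constant_feature_excluded_with_warning(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "flat": [5.0] * 4,
                           "y": [2.0, 1, 4, 3]})
        with pytest.warns(UserWarning, match="constant"):
            sim = spearman_adjacency(df)
        assert "flat" not in sim.features

    def test_all_constant_raises(self):
        df = pd.DataFrame({"a": [1.0] * 4, "b": [2.0] * 4})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="constant"):
                spearman_adjacency(df)

    def test_too_few_joint_observations_raise(self):
        df = pd.DataFrame(
            {"a": [1.0, 2, np.nan, np.nan, 3], "b": [np.nan, np.nan, 1.0, 2, 3]}
        )
        with pytest.raises(ValueError, match="jointly"):
            spearman_adjacency(df)


class TestMutualKnnGraph:
    def test_three_feature_hand_case(self):
        # AB=0.9, BC=0.8, AC=0.5 with k=1: A and B choose each other; C
        # chooses B but B prefers A, so C stays isolated.
        m = np.array([[1.0, 0.9, 0.5], [0.9, 1.0, 0.8], [0.5, 0.8, 1.0]])
        g = mutual_knn_graph(sim_from(m, ["A", "B", "C"]), k=1)
        assert set(g.edges) == {("A", "B")}
        assert g.degree["C"] == 0

    def test_asymmetric_nearest_neighbors_make_no_edge(self):
        # u's NN is v, but v's NN is w
        m = np.array([[1.0, 0.6, 0.1], [0.6, 1.0, 0.9], [0.1, 0.9, 1.0]])
        g = mutual_knn_graph(sim_from(m, ["u", "v", "w"]), k=1)
        assert ("u", "v") not in g.edges and ("v", "u") not in g.edges

    def test_max_degree_bounded_by_k(self):
        rng = np.random.default_rng(13)
        for k in (1, 2, 4):
            a = rng.random((12, 12))
            m = (a + a.T) / 2
            np.fill_diagonal(m, 1.0)
            g = mutual_knn_graph(sim_from(m, [f"f{i}" for i in range(12)]), k=k)
            assert max(dict(g.degree).values()) <= k

    def test_mutual_graph_is_subgraph_of_directed_knn(self):
        rng = np.random.default_rng(29)
        a = rng.random((10, 10))
        m = (a + a.T) / 2
        np.fill_diagonal(m, 1.0)
        names = [f"f{i}" for i in range(10)]
        k = 3
        g = mutual_knn_graph(sim_from(m, names), k=k)
        # recompute directed top-k neighbor lists independently
        topk = {}
        for i, f in enumerate(names):
            order = sorted(
                (j for j in range(10) if j != i),
                key=lambda j: (-m[i, j], names[j]),
            )
            topk[f] = {names[j] for j in order[:k]}
        for u, v in g.edges:
            assert v in topk[u] and u in topk[v]

    def test_absolute_mode_treats_anticorrelation_as_near(self):
        m = np.array([[1.0, -0.95, 0.2], [-0.95, 1.0, 0.1], [0.2, 0.1, 1.0]])
        names = ["a", "b", "c"]
        signed = mutual_knn_graph(sim_from(m, names), k=1, similarity="signed")
        assert ("a", "b") not in signed.edges
        absolute = mutual_knn_graph(sim_from(m, names), k=1, similarity="absolute")
        assert ("a", "b") in absolute.edges

    def test_k_out_of_range_raises(self):
        m = np.eye(3)
        with pytest.raises(ValueError):
            mutual_knn_graph(sim_from(m, ["a", "b", "c"]), k=3)

    def test_graph_invariant_to_monotone_feature_transform(self):
        table, _ = planted_two_block_table(seed=7, n_samples=80, per_block=5)
        g1 = mutual_knn_graph(spearman_adjacency(table), k=3)
        warped = table.copy()
        warped["b0_f00"] = np.exp(warped["b0_f00"])
        warped["b1_f02"] = warped["b1_f02"] ** 3
        g2 = mutual_knn_graph(spearman_adjacency(warped), k=3)
        assert set(g1.edges) == set(g2.edges)


class TestLouvainPartition:
    def test_two_disconnected_cliques_form_two_clusters(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        out = louvain_partition(g, seed=0)
        clusters = {out.nodes[n]["cluster"] for n in out.nodes}
        assert len(clusters) == 2
        for u, v in g.edges:
            assert out.nodes[u]["cluster"] == out.nodes[v]["cluster"]

    def test_edgeless_graph_gives_singletons(self):
        g = nx.empty_graph(4)
        out = louvain_partition(g, seed=0)
        assert len({out.nodes[n]["cluster"] for n in out.nodes}) == 4

    def test_seeded_partition_is_reproducible(self):
        g, labels = _planted_partition_graph(seed=3)
        p1 = louvain_partition(g, seed=5)
        p2 = louvain_partition(g, seed=5)
        assert all(
            p1.nodes[n]["cluster"] == p2.nodes[n]["cluster"] for n in g.nodes
        )

    def test_planted_partition_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        good = 0
        g, labels = _planted_partition_graph(seed=1)
        truth = [labels[n] for n in sorted(g.nodes)]
        for seed in range(20):
            out = louvain_partition(g, seed=seed)
            pred = [out.nodes[n]["cluster"] for n in sorted(g.nodes)]
            if adjusted_rand_score(truth, pred) >= 0.9:
                good += 1
        assert good >= 19


def _planted_partition_graph(seed, per_block=20, p_in=0.4, p_out=0.02):
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:02d}" for i in range(2 * per_block)]
    labels = {n: int(i >= per_block) for i, n in enumerate(nodes)}
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            p = p_in if labels[nodes[i]] == labels[nodes[j]] else p_out
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j])
    return g, labels


class TestPrioritizeFeatures:
    def _toy_graph(self):
        # clinical -- a -- b, c isolated; d and e are twins attached to a
        g = nx.Graph()
        g.add_nodes_from(["clin", "a", "b", "c", "d", "e"])
        g.add_edges_from([("clin", "a"), ("a", "b"), ("a", "d"), ("a", "e"),
                          ("d", "e")])
        for n in g.nodes:
            g.nodes[n]["cluster"] = 0 if n != "c" else 1
        return g

    def test_distance_ordering_and_ranks(self):
        report = prioritize_features(self._toy_graph(), ["clin"])
        feats = report.features
        assert feats.loc["clin", "distance"] == 0
        assert feats.loc["a", "distance"] == 1
        assert feats.loc["b", "distance"] == 2
        assert feats.loc["a", "rank"] < feats.loc["b", "rank"]

    def test_isolated_feature_flagged_unrelated(self):
        report = prioritize_features(self._toy_graph(), ["clin"])
        assert report.features.loc["c", "unrelated"]
        assert np.isinf(report.features.loc["c", "distance"])
        assert report.features.loc["c", "rank"] == len(report.features)

    def test_identical_closed_neighborhoods_flagged_redundant(self):
        report = prioritize_features(self._toy_graph(), ["clin"])
        assert report.features.loc["d", "redundant"]
        assert report.features.loc["e", "redundant"]
        assert not report.features.loc["a", "redundant"]

    def test_duplicated_feature_column_is_redundant_end_to_end(self):
        # hub feature duplicated verbatim: the copies are everyone's top
        # neighbors, end up adjacent with identical closed neighborhoods
        rng = np.random.default_rng(2)
        z = rng.standard_normal(120)
        table = pd.DataFrame(
            {"hub": 0.95 * z + 0.3 * rng.normal(size=120)}
            | {f"f{i}": 0.6 * z + 0.5 * rng.normal(size=120) for i in range(4)}
        )
        table["hub_dup"] = table["hub"]
        sim = spearman_adjacency(table)
        g = louvain_partition(mutual_knn_graph(sim, k=3), seed=0)
        report = prioritize_features(g, ["f0"])
        assert report.features.loc["hub_dup", "redundant"]
        assert report.features.loc["hub", "redundant"]

    def test_missing_clinical_raises(self):
        with pytest.raises(ValueError, match="clinical"):
            prioritize_features(self._toy_graph(), ["nope"])

    def test_cluster_summary_contains_every_cluster(self):
        report = prioritize_features(self._toy_graph(), ["clin"])
        assert set(report.clusters.index) == {0, 1}
        assert report.clusters.loc[0, "size"] == 5


class TestSetDistance:
    def test_shared_node_gives_zero(self):
        g = nx.path_graph(4)
        assert set_distance(g, [0, 1], [1, 2]) == 0.0

    def test_path_length_counted_in_edges(self):
        g = nx.path_graph(5)
        assert set_distance(g, [0], [4]) == 4.0

    def test_disconnected_sets_are_infinitely_far(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("c")
        assert np.isinf(set_distance(g, ["a"], ["c"]))
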