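"""Network construction, Table-style metrics and pooled eigencentrality."""

import math

import networkx as nx
import numpy as np
import pytest

from traitnet import (
    NetworkError,
    TraitNetwork,
    build_network,
    compute_metrics,
    count_category_connections,
    export_network,
    mean_node_eigencentrality,
    pooled_eigencentrality,
    power_iteration_scores,
)
from traitnet.cooccurrence import cooccurrence_pvalues, TraitPairStat
from conftest import make_trait_matrix


def stat(mod_i, mod_j, q_obs, n=10, n_i=5, n_j=5):
    p_lt, p_gt = cooccurrence_pvalues(n_i, n_j, n, q_obs)
    return TraitPairStat(mod_i=mod_i, mod_j=mod_j, n=n, n_i=n_i, n_j=n_j,
                         q_obs=q_obs, expected=n_i * n_j / n,
                         p_lt=p_lt, p_gt=p_gt)


def net_from_edges(edges, site="s", treatment="control", categories=None):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    for node in g.nodes:
        g.nodes[node]["category"] = (categories or {}).get(node, "REG")
    return TraitNetwork(site=site, treatment=treatment, graph=g)


class TestBuildNetwork:
    def test_nodes_and_edges_from_retained_pairs(self):
        pairs = [stat("a", "b", 2), stat("b", "c", 3), stat("c", "d", 5)]
        net = build_network(pairs, "s1", "control")
        assert net.n_nodes == 4
        assert net.n_connections == 3
        assert net.graph.edges["b", "c"]["weight"] == 3

    def test_empty_retained_list(self):
        net = build_network([], "s1", "high")
        assert net.n_nodes == 0 and net.n_connections == 0

    def test_weights_pass_through(self):
        net = build_network([stat("a", "b", 2), stat("c", "d", 5)], "s", "control")
        assert sorted(d["weight"] for _, _, d in net.graph.edges(data=True)) == [2, 5]

    def test_duplicate_pair_rejected(self):
        with pytest.raises(NetworkError, match="duplicate"):
            build_network([stat("a", "b", 2), stat("a", "b", 3)], "s", "control")

    def test_category_attributes_from_trait_table(self, small_traits):
        net = build_network([stat("m0", "m1", 2)], "s", "control", small_traits)
        assert net.graph.nodes["m0"]["category"] == "REG"
        assert net.graph.nodes["m1"]["category"] == "REC_e"


class TestCategoryConnections:
    def test_counts_unordered_category_pairs(self):
        net = net_from_edges(
            [("r1", "e1", 1), ("r1", "e2", 2), ("r2", "i1", 1)],
            categories={"r1": "REG", "r2": "REG", "e1": "REC_e",
                        "e2": "REC_e", "i1": "RES_i"},
        )
        assert count_category_connections(net, "REG", "REC_e") == 2
        assert count_category_connections(net, "REC_e", "REG") == 2
        assert count_category_connections(net, "REG", "RES_e") == 0

    def test_within_category_edges(self):
        net = net_from_edges([("r1", "r2", 1)],
                             categories={"r1": "REG", "r2": "REG"})
        assert count_category_connections(net, "REG", "REG") == 1
        assert count_category_connections(net, "REG", "REC_e") == 0


class TestPowerIteration:
    def test_triangle_symmetry(self):
        g = nx.complete_graph(3)
        scores = power_iteration_scores(g)
        assert all(s == pytest.approx(1.0) for s in scores.values())

    def test_star_converges_to_closed_form(self):
        g = nx.star_graph(3)  # hub 0, three leaves
        scores = power_iteration_scores(g, iterations=5000, tol=1e-14)
        assert scores[0] == pytest.approx(1.0)
        for leaf in (1, 2, 3):
            assert scores[leaf] == pytest.approx(1 / math.sqrt(3), abs=1e-6)

    def test_subdominant_component_stays_below_at_default_iterations(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.path_graph(2))
        scores = power_iteration_scores(g, iterations=100)
        triangle = [scores[i] for i in range(3)]
        edge = [scores[i] for i in (3, 4)]
        assert min(triangle) > max(edge) > 0.0

    def test_isolated_nodes_score_zero(self):
        g = nx.complete_graph(3)
        g.add_node("isolated")
        scores = power_iteration_scores(g)
        assert scores["isolated"] == 0.0
        assert max(scores.values()) == 1.0

    def test_matches_dense_oracle_on_random_connected_graphs(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 9))
            g = nx.gnp_random_graph(n, 0.6, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                continue
            scores = power_iteration_scores(g, iterations=20000, tol=1e-14)
            a = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
            _, vecs = np.linalg.eigh(a)
            v = np.abs(vecs[:, -1])
            v /= v.max()
            got = np.array([scores[i] for i in sorted(g.nodes)])
            np.testing.assert_allclose(got, v, atol=1e-6)


class TestPooledEigencentrality:
    def test_keys_are_site_treatment_modality(self):
        nets = [net_from_edges([("a", "b", 1)], site="s1"),
                net_from_edges([("a", "b", 1)], site="s2")]
        scores = pooled_eigencentrality(nets)
        assert set(scores) == {("s1", "control", "a"), ("s1", "control", "b"),
                               ("s2", "control", "a"), ("s2", "control", "b")}
        assert max(scores.values()) == 1.0

    def test_all_empty_networks_rejected(self):
        with pytest.raises(NetworkError):
            pooled_eigencentrality([build_network([], "s", "control")])

    def test_isolated_copy_preserves_ordering(self):
        tri = [("a", "b", 1), ("b", "c", 1), ("a", "c", 1)]
        path = [("x", "y", 1), ("y", "z", 1)]
        nets = [net_from_edges(tri, site="s1"), net_from_edges(path, site="s2")]
        base = pooled_eigencentrality(nets)
        with_copy = pooled_eigencentrality(
            nets + [net_from_edges(path, site="s3")])
        for k1 in base:
            for k2 in base:
                if base[k1] > base[k2]:
                    assert with_copy[k1] > with_copy[k2]

    def test_per_component_scaled_matches_eigen_oracle(self):
        tri = net_from_edges([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)],
                             site="s1")
        path = net_from_edges([("x", "y", 1), ("y", "z", 1)], site="s2")
        scores = pooled_eigencentrality([tri, path], mode="per_component_scaled")
        # triangle: lambda = 2, symmetric -> all 1.0; path: lambda = sqrt(2),
        # centre 1 scaled by sqrt(2)/2
        for m in ("a", "b", "c"):
            assert scores[("s1", "control", m)] == pytest.approx(1.0)
        assert scores[("s2", "control", "y")] == pytest.approx(
            math.sqrt(2) / 2, abs=1e-9)

    def test_weighted_flag_changes_scores(self):
        nets = [net_from_edges([("a", "b", 10), ("b", "c", 1)], site="s1")]
        unweighted = pooled_eigencentrality(nets, iterations=500)
        weighted = pooled_eigencentrality(nets, iterations=500, weighted=True)
        key_a = ("s1", "control", "a")
        key_c = ("s1", "control", "c")
        assert unweighted[key_a] == pytest.approx(unweighted[key_c])
        assert weighted[key_a] > weighted[key_c]

    def test_unknown_mode_rejected(self):
        with pytest.raises(NetworkError, match="mode"):
            pooled_eigencentrality([net_from_edges([("a", "b", 1)])],
                                   mode="exactly")


class TestMetrics:
    def test_mean_eigencentrality_is_arithmetic_mean(self):
        net = net_from_edges([("a", "b", 1), ("b", "c", 1)], site="s1")
        scores = {("s1", "control", "a"): 1.0, ("s1", "control", "b"): 0.5,
                  ("s1", "control", "c"): 0.0}
        assert mean_node_eigencentrality(scores, net) == pytest.approx(0.5)

    def test_empty_network_scores_zero_with_warning(self, caplog):
        net = build_network([], "s1", "high")
        with caplog.at_level("WARNING"):
            assert mean_node_eigencentrality({}, net) == 0.0
        assert "empty network" in caplog.text

    def test_missing_scores_rejected(self):
        net = net_from_edges([("a", "b", 1)], site="s1")
        with pytest.raises(NetworkError):
            mean_node_eigencentrality({}, net)

    def test_count_metrics(self):
        net = net_from_edges(
            [("r", "e", 2), ("r", "x", 1), ("e", "x", 1)],
            site="s1",
            categories={"r": "REG", "e": "REC_e", "x": "RES_e"},
        )
        scores = {("s1", "control", m): 0.5 for m in "rex"}
        m = compute_metrics(net, scores)
        assert (m.n_nodes, m.n_connections) == (3, 3)
        assert (m.n_reg_rece, m.n_reg_rese) == (1, 1)
        assert m.n_reg_rece + m.n_reg_rese <= m.n_connections
        assert m.mean_eigencentrality == pytest.approx(0.5)

    def test_metrics_invariant_under_relabeling(self):
        cats = {"a": "REG", "b": "REC_e", "c": "RES_e"}
        edges = [("a", "b", 2), ("b", "c", 1)]
        relabeled = [("x" + u, "x" + v, w) for u, v, w in edges]
        n1 = net_from_edges(edges, site="s1", categories=cats)
        n2 = net_from_edges(relabeled, site="s1",
                            categories={"x" + k: v for k, v in cats.items()})
        s1 = {("s1", "control", m): 0.3 for m in "abc"}
        s2 = {("s1", "control", "x" + m): 0.3 for m in "abc"}
        m1, m2 = compute_metrics(n1, s1), compute_metrics(n2, s2)
        assert (m1.n_nodes, m1.n_connections, m1.n_reg_rece, m1.n_reg_rese,
                m1.mean_eigencentrality) == \
               (m2.n_nodes, m2.n_connections, m2.n_reg_rece, m2.n_reg_rese,
                m2.mean_eigencentrality)


class TestExport:
    def test_gexf_round_trip(self, tmp_path):
        net = net_from_edges([("a", "b", 2), ("b", "c", 1)], site="s1",
                             categories={"a": "REG", "b": "REC_e", "c": "RES_e"})
        scores = {("s1", "control", m): 0.5 for m in "abc"}
        path = tmp_path / "net.gexf"
        export_network(net, scores, path, fmt="gexf")
        back = nx.read_gexf(path)
        assert nx.is_isomorphic(net.graph, back)
        assert {d["weight"] for _, _, d in back.edges(data=True)} == {1, 2}

    def test_graphml_round_trip_preserves_attributes(self, tmp_path):
        net = net_from_edges([("a", "b", 3)], site="s1",
                             categories={"a": "REG", "b": "RES_e"})
        path = tmp_path / "net.graphml"
        export_network(net, {("s1", "control", "a"): 1.0,
                             ("s1", "control", "b"): 0.25}, path, fmt="graphml")
        back = nx.read_graphml(path)
        assert back.nodes["a"]["category"] == "REG"
        assert back.nodes["b"]["eigencentrality"] == pytest.approx(0.25)

    def test_seeded_layout_is_deterministic(self, tmp_path):
        net = net_from_edges([("a", "b", 1), ("b", "c", 2)], site="s1")
        p1, p2 = tmp_path / "n1.graphml", tmp_path / "n2.graphml"
        export_network(net, None, p1, fmt="graphml", layout_seed=7)
        export_network(net, None, p2, fmt="graphml", layout_seed=7)
        assert p1.read_text() == p2.read_text()

    def test_unknown_format_rejected(self, tmp_path):
        net = net_from_edges([("a", "b", 1)])
        with pytest.raises(NetworkError, match="format"):
            export_network(net, None, tmp_path / "x.dot", fmt="dot")
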