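import networkx as nx
import numpy as np
import pandas as pd
import pytest

from targetpri.crosstalk import (
    CrosstalkConfig,
    build_pathway_network,
    label_nodes,
    max_scoring_subnet,
    permutation_test,
    size_search,
    subnet_score,
)

from conftest import brute_force_subnet, random_connected_graph


class TestBuildPathwayNetwork:
    def test_union_with_provenance(self):
        net = build_pathway_network({"P1": [("A", "B")], "P2": [("A", "B"), ("B", "C")]})
        assert set(net.edges) == {("A", "B"), ("B", "C")}
        assert net["A"]["B"]["pathways"] == ("P1", "P2")
        assert net["B"]["C"]["pathways"] == ("P2",)

    def test_single_pathway_identity(self):
        net = build_pathway_network({"P1": [("A", "B"), ("B", "C")]})
        assert net.number_of_edges() == 2

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError):
            build_pathway_network({})


class TestMaxScoringSubnet:
    def test_steiner_node_bridges_two_prizes(self):
        g = nx.path_graph(["A", "B", "C"])
        scores = {"A": 5.0, "B": 0.0, "C": 5.0}
        s = max_scoring_subnet(g, scores, theta=1.0)
        assert s == {"A", "B", "C"}
        assert subnet_score(s, scores, 1.0) == pytest.approx(7.0)

    def test_theta_above_max_score_gives_empty(self):
        g = nx.path_graph(["A", "B"])
        assert max_scoring_subnet(g, {"A": 1.0, "B": 2.0}, theta=3.0) == set()

    def test_star_hub_included_as_steiner_node(self):
        g = nx.star_graph(["HUB", "L1", "L2", "L3", "L4"])
        scores = {"HUB": 0.0, "L1": 5.0, "L2": 5.0, "L3": 5.0, "L4": 0.1}
        theta = 1.0
        s = max_scoring_subnet(g, scores, theta)
        opt, opt_set = brute_force_subnet(g, scores, theta)
        assert s == opt_set == {"HUB", "L1", "L2", "L3"}
        assert subnet_score(s, scores, theta) == pytest.approx(opt)

    def test_connected_positives_recovered_exactly(self):
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(60):
            g = random_connected_graph(rng)
            scores = {v: float(rng.uniform(0, 10)) for v in g.nodes}
            theta = float(rng.uniform(0, 10))
            positives = {v for v in g.nodes if scores[v] > theta}
            if not positives or not nx.is_connected(g.subgraph(positives)):
                continue
            checked += 1
            s = max_scoring_subnet(g, scores, theta)
            opt, _ = brute_force_subnet(g, scores, theta)
            assert subnet_score(s, scores, theta) == pytest.approx(opt)
        assert checked >= 10

    def test_output_always_connected(self):
        rng = np.random.default_rng(5)
        for _ in range(80):
            g = random_connected_graph(rng)
            scores = {v: float(rng.uniform(0, 10)) for v in g.nodes}
            s = max_scoring_subnet(g, scores, float(rng.uniform(0, 10)))
            if s:
                assert nx.is_connected(g.subgraph(s))

    def test_positives_spanning_components_pick_best_one(self):
        g = nx.Graph([("A", "B"), ("X", "Y")])
        scores = {"A": 2.0, "B": 2.0, "X": 9.0, "Y": 0.0}
        s = max_scoring_subnet(g, scores, theta=1.0)
        assert s == {"X"}


class TestSizeSearch:
    def test_size_monotone_in_theta(self):
        rng = np.random.default_rng(1)
        g = nx.barabasi_albert_graph(50, 2, seed=2)
        scores = {v: float(s) for v, s in enumerate(rng.uniform(0, 1, 50))}
        sizes = [
            len(max_scoring_subnet(g, scores, t))
            for t in np.quantile(list(scores.values()), np.linspace(0, 0.95, 12))
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_two_node_network_desired_two(self):
        g = nx.path_graph(["A", "B"])
        res = size_search(g, {"A": 1.0, "B": 2.0}, CrosstalkConfig(desired_nodes=2))
        assert set(res.nodes) == {"A", "B"}

    def test_desired_exceeding_network_rejected(self):
        g = nx.path_graph(["A", "B"])
        with pytest.raises(ValueError):
            size_search(g, {"A": 1.0, "B": 1.0}, CrosstalkConfig(desired_nodes=5))

    def test_hits_reachable_sizes_within_tolerance(self):
        rng = np.random.default_rng(7)
        g = nx.barabasi_albert_graph(80, 2, seed=3)
        g = nx.relabel_nodes(g, {v: f"g{v:02d}" for v in g.nodes})
        scores = {v: float(s) for v, s in zip(sorted(g.nodes), rng.uniform(0, 1, 80))}
        for desired in (10, 20, 30):
            cfg = CrosstalkConfig(desired_nodes=desired)
            res = size_search(g, scores, cfg)
            grid_sizes = {
                len(max_scoring_subnet(g, scores, float(t)))
                for t in np.unique(list(scores.values()))
            }
            if any(abs(s - desired) <= cfg.size_tolerance for s in grid_sizes):
                assert abs(len(res.nodes) - desired) <= cfg.size_tolerance
            assert nx.is_connected(g.subgraph(res.nodes))

    def test_auto_uses_90th_percentile(self):
        g = nx.path_graph([f"n{i}" for i in range(10)])
        scores = {f"n{i}": float(i) for i in range(10)}
        res = size_search(g, scores, CrosstalkConfig(desired_nodes="auto"))
        assert res.theta_star == pytest.approx(np.quantile(list(scores.values()), 0.9))


class TestPermutationTest:
    def test_all_equal_scores_give_p_one(self):
        g = nx.barabasi_albert_graph(30, 2, seed=4)
        scores = {v: 1.0 for v in g.nodes}
        cfg = CrosstalkConfig(desired_nodes=5, n_permutations=19, seed=0)
        obs = size_search(g, scores, cfg)
        p_emp, _, null = permutation_test(g, scores, obs, cfg)
        assert p_emp == 1.0
        assert all(s == pytest.approx(obs.subnet_score) for s in null)

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(9)
        g = nx.barabasi_albert_graph(40, 2, seed=5)
        scores = {v: float(s) for v, s in enumerate(rng.exponential(1, 40))}
        cfg = CrosstalkConfig(desired_nodes=8, n_permutations=33, seed=123)
        obs = size_search(g, scores, cfg)
        out1 = permutation_test(g, scores, obs, cfg)
        out2 = permutation_test(g, scores, obs, cfg)
        assert out1 == out2
        assert out1[0] >= 1 / 34

    def test_degree_multiset_preserved_within_bins(self):
        from targetpri.crosstalk import _degree_groups

        g = nx.barabasi_albert_graph(50, 3, seed=6)
        nodes = sorted(g.nodes)
        groups = _degree_groups(g, nodes, 10)
        assert sorted(i for grp in groups for i in grp) == list(range(len(nodes)))
        groups_exact = _degree_groups(g, nodes, 0)
        for grp in groups_exact:
            degs = {g.degree(nodes[i]) for i in grp}
            assert len(degs) == 1

    def test_planted_module_is_significant(self, pathway_network):
        from targetpri.fixtures import planted_node_scores

        spec, net, planted = pathway_network
        scores = planted_node_scores(spec, net, planted)
        cfg = CrosstalkConfig(desired_nodes=len(planted), n_permutations=99, seed=1)
        obs = size_search(net, scores, cfg)
        p_emp, p_approx, _ = permutation_test(net, scores, obs, cfg)
        assert p_emp == pytest.approx(1 / 100)
        assert p_approx < 0.01


class TestLabelNodes:
    def _priority(self):
        return pd.DataFrame(
            {"gene": ["A", "B"], "rank": [1, 2], "rating": [4.97, 3.5]}
        )

    def test_label_format(self):
        from targetpri.crosstalk import CrosstalkResult

        res = CrosstalkResult(["A"], {"A": 1.0}, [], 1.0, 0.0)
        label_nodes(res, self._priority())
        assert res.labels == {"A": "4.97®1"}

    def test_missing_gene_named_in_error(self):
        from targetpri.crosstalk import CrosstalkResult

        res = CrosstalkResult(["ZZ"], {"ZZ": 1.0}, [], 1.0, 0.0)
        with pytest.raises(KeyError, match="ZZ"):
            label_nodes(res, self._priority())
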