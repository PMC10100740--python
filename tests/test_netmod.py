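import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from fmtnet import (
    build_network,
    classify_key_peripheral,
    greedy_modules,
    indicator_subnetwork,
    modules_from_network,
    rmt_threshold,
    topology,
)
from fmtnet.netmod import brute_force_modularity
from fmtnet.sparcc import CorrelationMatrix


def _corr(ids, r, p):
    return CorrelationMatrix(list(ids), np.asarray(r, dtype=float),
                             np.asarray(p, dtype=float))


def _two_triangles() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("x", "y"), ("y", "z"), ("x", "z")])
    return g


class TestRmtThreshold:
    def test_block_structure_transition_in_band(self):
        # planted blocks at 0.7 over noise dense up to |r| < 0.2: the
        # spacing statistics switch from Wigner to Poisson at the noise
        # ceiling, so the scan must land between ceiling and block level
        rng = np.random.default_rng(0)
        n = 60
        mag = rng.uniform(0.12, 0.2, size=(n, n))
        sign = rng.choice([-1.0, 1.0], size=(n, n))
        r = np.triu(mag * sign, 1)
        r = r + r.T
        for s in range(0, 20, 5):
            idx = np.arange(s, s + 5)
            r[np.ix_(idx, idx)] = 0.7
        np.fill_diagonal(r, 1.0)
        cut = rmt_threshold(CorrelationMatrix([str(i) for i in range(n)], r))
        assert 0.2 <= cut < 0.7

    def test_fallback_default_when_no_transition(self, caplog):
        # a matrix too small for any spacing statistics always falls back
        r = np.eye(5)
        with caplog.at_level("WARNING"):
            cut = rmt_threshold(CorrelationMatrix(list("abcde"), r))
        assert cut == 0.3

    def test_noise_matrix_low_cutoff(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 200))
        r = np.corrcoef(x)
        cut = rmt_threshold(CorrelationMatrix([str(i) for i in range(40)], r))
        assert cut <= 0.35


class TestBuildNetwork:
    def test_all_p_one_empty(self):
        r = np.full((4, 4), 0.9)
        np.fill_diagonal(r, 1.0)
        net = build_network(_corr("abcd", r, np.ones((4, 4))))
        assert net.number_of_edges() == 0

    def test_threshold_logic_by_hand(self):
        # only the (0,1) pair passes both |r| >= 0.3 and p < 0.05
        r = np.eye(4)
        p = np.ones((4, 4))
        r[0, 1] = r[1, 0] = 0.5
        p[0, 1] = p[1, 0] = 0.01
        r[2, 3] = r[3, 2] = 0.2
        p[2, 3] = p[3, 2] = 0.01
        r[0, 2] = r[2, 0] = 0.9
        p[0, 2] = p[2, 0] = 0.5
        net = build_network(_corr(["t1", "t2", "t3", "t4"], r, p))
        assert set(net.edges) == {("t1", "t2")}
        assert net.edges["t1", "t2"]["r"] == pytest.approx(0.5)

    def test_signed_positive_mode_drops_negative(self):
        r = np.eye(4)
        p = np.full((4, 4), 0.001)
        r[0, 1] = r[1, 0] = -0.8
        r[2, 3] = r[3, 2] = 0.8
        net = build_network(_corr("abcd", r, p), signed="positive")
        assert set(net.edges) == {("c", "d")}

    def test_mismatched_matrices_rejected(self):
        r = np.eye(4)
        with pytest.raises(ValueError, match="mismatched"):
            build_network(_corr("abcd", r, np.ones((3, 3))))


class TestIndicatorSubnetwork:
    def test_disjoint_indicator_set_empty(self, caplog):
        with caplog.at_level("WARNING"):
            sub = indicator_subnetwork(_two_triangles(), {"nope"})
        assert sub.number_of_nodes() == 0

    def test_star_center_keeps_whole_star(self):
        star = nx.star_graph(5)
        sub = indicator_subnetwork(star, {0})
        assert set(sub.nodes) == set(star.nodes)
        assert sub.number_of_edges() == star.number_of_edges()

    def test_path_neighbor_rule(self):
        path = nx.path_graph(["a", "b", "c"])
        sub = indicator_subnetwork(path, {"a"})
        assert set(sub.nodes) == {"a", "b"}
        assert set(sub.edges) == {("a", "b")}

    def test_subgraph_and_idempotent(self):
        g = _two_triangles()
        sub = indicator_subnetwork(g, {"a"})
        assert set(sub.edges) <= set(g.edges)
        again = indicator_subnetwork(sub, {"a"})
        assert set(again.edges) == set(sub.edges)


class TestGreedyModules:
    def test_two_triangles_q_exact(self):
        comms, q = greedy_modules(_two_triangles())
        assert len(comms) == 2
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_single_clique_one_community_zero_q(self):
        comms, q = greedy_modules(nx.complete_graph(5))
        assert len(comms) == 1
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_edgeless_rejected(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        with pytest.raises(ValueError, match="edge"):
            greedy_modules(g)

    def test_planted_partition_recovered(self):
        g = nx.planted_partition_graph(4, 10, 0.8, 0.05, seed=1)
        comms, _ = greedy_modules(g)
        labels = {n: i for i, c in enumerate(comms) for n in c}
        found = [labels[n] for n in g.nodes]
        true = [n // 10 for n in g.nodes]
        assert adjusted_rand_score(true, found) > 0.9

    def test_q_matches_brute_force_oracle(self):
        fixtures = [_two_triangles(), nx.karate_club_graph(),
                    nx.planted_partition_graph(3, 8, 0.7, 0.1, seed=2)]
        for g in fixtures:
            comms, q = greedy_modules(g)
            assert q == pytest.approx(brute_force_modularity(g, comms), abs=1e-12)


class TestClassification:
    def test_every_community_with_indicator_no_na(self):
        comms = [{"a", "b", "c"}, {"x", "y", "z"}]
        part = classify_key_peripheral(comms, {"a", "x"})
        assert part.peripheral_species() == set()

    def test_no_indicators_all_na(self):
        comms = [{"a", "b", "c"}, {"x", "y", "z"}]
        part = classify_key_peripheral(comms, set())
        assert part.key_species() == set()
        assert part.module_names == []

    def test_size_rule_and_labels(self):
        comms = [{"p", "q", "r"}, {"a", "b", "c", "d", "e"}]
        part = classify_key_peripheral(comms, {"a"})
        assert part.members("M1") == {"a", "b", "c", "d", "e"}
        assert all(part.labels[n] == "NA" for n in "pqr")

    def test_min_module_size_demotes_tiny(self):
        comms = [{"a", "b"}, {"x", "y", "z"}]
        part = classify_key_peripheral(comms, {"a", "x"}, min_module_size=3)
        assert part.labels["a"] == "NA"
        assert part.labels["x"] == "M1"

    def test_modules_ordered_by_decreasing_size(self):
        comms = [{"a", "b", "c"}, {"u", "v", "w", "x"}, {"m", "n", "o"}]
        part = classify_key_peripheral(comms, {"a", "u", "m"})
        assert len(part.members("M1")) == 4
        # ties by smallest member id: {a,b,c} before {m,n,o}
        assert part.members("M2") == {"a", "b", "c"}


class TestTopology:
    def test_two_triangle_fixture_counts(self):
        g = _two_triangles()
        part = modules_from_network(g, {"a", "x"})
        topo = topology(g, part)
        assert (topo["n_nodes"], topo["n_edges"], topo["n_modules"]) == (6, 6, 2)
        assert topo["modularity"] == pytest.approx(0.5, abs=1e-12)

    def test_empty_network_zeros(self):
        topo = topology(nx.Graph())
        assert topo == {"n_nodes": 0, "n_edges": 0}

    def test_invariant_to_relabeling(self):
        g = _two_triangles()
        part = modules_from_network(g, {"a"})
        h = nx.relabel_nodes(g, {n: n.upper() for n in g.nodes})
        part_h = modules_from_network(h, {"A"})
        ta, th = topology(g, part), topology(h, part_h)
        assert (ta["n_nodes"], ta["n_edges"], ta["n_modules"]) == \
               (th["n_nodes"], th["n_edges"], th["n_modules"])


class TestEndToEndModules:
    def test_planted_blocks_recovered_nonblock_na(self):
        """Planted correlation blocks become indicator modules; taxa outside
        the blocks stay out of the key set at >= 80% rate over 10 seeds."""
        from fmtnet import SparccConfig, basis_correlations, sparcc_pvalues

        basis = None
        from fmtnet import make_basis, simulate_counts

        basis = make_basis(np.zeros(50), blocks=(5, 5, 5), block_corr=0.7)
        block_taxa = {f"t{i}" for i in range(15)}
        indicators = {"t0", "t5", "t10"}  # one planted indicator per block
        na_rates, block_hits = [], []
        for seed in range(10):
            table = simulate_counts(basis, 100, seed=seed)
            cfg = SparccConfig(n_boot=60, seed=seed)
            cm = basis_correlations(table, cfg)
            p = sparcc_pvalues(table, cm, cfg)
            net = build_network(cm, p)
            sub = indicator_subnetwork(net, indicators)
            part = modules_from_network(sub, indicators)
            key = part.key_species()
            nonblock = set(table.asv_ids) - block_taxa
            na_rates.append(1.0 - len(key & nonblock) / len(nonblock))
            block_hits.append(len(key & block_taxa) / len(block_taxa))
        assert np.median(block_hits) >= 0.8
        assert np.median(na_rates) >= 0.8
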