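"""Group-level statistics: density, reciprocity, centralization, modularity."""

import itertools

import numpy as np
import pytest

from agonet import group_metrics as gm
from agonet.centrality import degree_centralities
from agonet.synthetic import SimConfig, simulate_pen, build_pen_network

from _oracles import (
    all_digraphs,
    brute_degrees,
    brute_density,
    brute_reciprocity,
    make_net,
    rand_index,
    random_digraph,
)


def _all_degree_scores(net):
    _, _, all_d = degree_centralities(net)
    return {a: float(v) for a, v in all_d.items()}


class TestDensityReciprocity:
    def test_density_formula(self):
        net = make_net([(0, 1), (1, 0)], n=3)
        assert gm.density(net) == pytest.approx(2 / 6)

    def test_density_bounds(self):
        assert gm.density(make_net([], n=5)) == 0.0
        complete = make_net(
            [(i, j) for i in range(4) for j in range(4) if i != j]
        )
        assert gm.density(complete) == 1.0

    def test_reciprocity_partial(self):
        net = make_net([(0, 1), (1, 0), (0, 2)], n=3)
        assert gm.reciprocity(net) == pytest.approx(2 / 3)

    def test_reciprocity_bounds(self):
        dag = make_net([(0, 1), (0, 2), (1, 2)], n=3)
        assert gm.reciprocity(dag) == 0.0
        sym = make_net([(0, 1), (1, 0), (1, 2), (2, 1)], n=3)
        assert gm.reciprocity(sym) == 1.0

    def test_edgeless_reciprocity_warns_zero(self):
        with pytest.warns(UserWarning, match="edgeless"):
            assert gm.reciprocity(make_net([], n=4)) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        edges = random_digraph(rng, 10, 0.25) or [(0, 1)]
        net = make_net(edges, n=10)
        assert gm.density(net) == pytest.approx(brute_density(edges, 10))
        assert gm.reciprocity(net) == pytest.approx(brute_reciprocity(edges))

    def test_invariant_to_weight_scaling(self):
        edges = [(0, 1), (1, 0), (2, 3)]
        a = make_net(edges, n=4, weights=[1, 1, 1])
        b = make_net(edges, n=4, weights=[9, 9, 9])
        assert gm.density(a) == gm.density(b)
        assert gm.reciprocity(a) == gm.reciprocity(b)


class TestCentralization:
    def test_star_is_one_for_degree(self):
        star = gm._star_network(8)
        assert gm.centralization(
            _all_degree_scores(star), "degree"
        ) == pytest.approx(1.0, abs=1e-9)

    def test_complete_graph_is_zero_any_measure(self):
        net = make_net([(i, j) for i in range(5) for j in range(5) if i != j])
        for measure in gm.CENTRALIZATION_MEASURES:
            scores = gm._measure_scores(net, measure)
            assert gm.centralization(scores, measure) == pytest.approx(
                0.0, abs=1e-9
            )

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            gm.centralization({"a": 1.0, "b": 0.0}, "degree")

    def test_zero_iff_all_scores_equal(self):
        assert gm.centralization({"a": 2.0, "b": 2.0, "c": 2.0}, "degree") == 0
        assert gm.centralization({"a": 3.0, "b": 1.0, "c": 0.0}, "degree") > 0

    def test_star_attains_exhaustive_maximum_n4(self):
        """No 4-node digraph beats the star sum, for all- and out-degree."""
        n = 4
        max_all = max_out = 0.0
        for edges in all_digraphs(n):
            in_d, out_d, all_d = brute_degrees(edges, n)
            max_all = max(max_all, sum(max(all_d) - v for v in all_d))
            max_out = max(max_out, sum(max(out_d) - v for v in out_d))
        assert max_all == pytest.approx(gm._star_max("degree", n))
        # Freeman out-degree star: one node attacks everyone -> (n-1)^2
        assert max_out == pytest.approx((n - 1) ** 2)

    def test_all_measures_within_unit_interval_random_pens(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(5, 14))
            net = make_net(random_digraph(rng, n, rng.uniform(0.05, 0.6)), n=n)
            for measure in gm.CENTRALIZATION_MEASURES:
                c = gm.centralization(gm._measure_scores(net, measure), measure)
                assert 0.0 <= c <= 1.0


class TestModularity:
    def test_two_disconnected_triangles(self):
        net = make_net([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])
        part = {f"n{k}": k // 3 for k in range(6)}
        assert gm.modularity(net, part) == pytest.approx(0.5)

    def test_single_community_is_zero(self):
        net = make_net([(0, 1), (1, 2), (2, 0), (3, 4)], n=5)
        assert gm.modularity(net, {f"n{k}": 0 for k in range(5)}) == 0.0

    def test_unlabelled_node_fatal(self):
        net = make_net([(0, 1)], n=3)
        with pytest.raises(ValueError, match="unlabelled"):
            gm.modularity(net, {"n0": 0, "n1": 0})

    @pytest.mark.parametrize("seed", range(10))
    def test_bounded_for_random_partitions(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        net = make_net(random_digraph(rng, n, 0.3), n=n)
        part = {f"n{k}": int(rng.integers(0, 3)) for k in range(n)}
        assert -1.0 <= gm.modularity(net, part) <= 1.0


class TestDetectCommunities:
    def test_recovers_two_triangles_exactly(self):
        net = make_net([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])
        part = gm.detect_communities(net)
        assert len(set(part.values())) == 2
        assert part["n0"] == part["n1"] == part["n2"]
        assert part["n3"] == part["n4"] == part["n5"]
        # exhaustive check that this is the unique optimum over partitions
        # into two labelled halves is equivalent to Q = 0.5 being attained
        assert gm.modularity(net, part) == pytest.approx(0.5)

    def test_edgeless_gives_singletons_q_zero(self):
        net = make_net([], n=6)
        part = gm.detect_communities(net)
        assert len(set(part.values())) == 6
        assert gm.modularity(net, part) == 0.0

    def test_isolated_nodes_are_singletons(self):
        net = make_net([(0, 1), (1, 0)], n=4)
        part = gm.detect_communities(net)
        labels = [part[f"n{k}"] for k in range(4)]
        assert labels[2] != labels[3]
        assert labels[2] not in (labels[0], labels[1])

    @pytest.mark.parametrize("seed", range(20))
    def test_detected_q_never_negative(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        net = make_net(random_digraph(rng, n, rng.uniform(0.05, 0.7)), n=n)
        part = gm.detect_communities(net)
        assert gm.modularity(net, part) >= 0.0

    def test_bracketed_by_exhaustive_optimum_on_tiny_graphs(self):
        """Greedy Q is sandwiched between 0 and the exhaustive optimum."""
        rng = np.random.default_rng(9)
        for _ in range(15):
            n = 5
            net = make_net(random_digraph(rng, n, 0.4), n=n)
            greedy_q = gm.modularity(net, gm.detect_communities(net))
            best = 0.0
            nodes = [f"n{k}" for k in range(n)]
            for labels in itertools.product(range(n), repeat=n):
                q = gm.modularity(net, dict(zip(nodes, labels)))
                best = max(best, q)
            assert 0.0 <= greedy_q <= best + 1e-12

    def test_planted_two_block_recovery(self):
        """Strong within-block attack rates are recovered (Rand >= 0.9)."""
        config = SimConfig(
            pen_sizes=(12,),
            isolation_prob=0.0,
            community_blocks=2,
            block_factor=40.0,
            base_attack_rate=0.05,
            dominance_effect=0.3,
        )
        scores = []
        for seed in range(50):
            roster, records, latent = simulate_pen(config, seed, 0)
            net = build_pen_network(records, roster)
            part = gm.detect_communities(net)
            planted = dict(zip(latent["animal_id"], latent["block"]))
            scores.append(rand_index(planted, part))
        assert np.mean(scores) >= 0.9


def test_group_metrics_bundle_fields():
    net = make_net([(0, 1), (1, 0), (1, 2), (3, 1)], n=6, pen_id="p7")
    m = gm.group_metrics(net)
    assert m.pen_id == "p7" and m.n_animals == 6
    assert 0 <= m.density <= 1 and 0 <= m.reciprocity <= 1
    assert -1 <= m.modularity <= 1
    assert set(m.partition) == set(net.nodes)
    assert m.n_communities == len(set(m.partition.values()))
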