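"""PIN construction, topology summaries, KS statistic and the null comparison."""

from collections import Counter

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from degnet import network as net
from degnet.simulate import simulate_interactome


class TestBuildPIN:
    def test_first_degree_rule(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        pin = net.build_pin(["A"], g)
        assert set(pin.graph.nodes) == {"A", "B"}
        assert set(map(frozenset, pin.graph.edges())) == {frozenset({"A", "B"})}

    def test_all_nodes_as_seeds_recovers_interactome(self):
        g, _ = simulate_interactome(40, 2, seed=1)
        pin = net.build_pin(list(g.nodes), g)
        assert nx.utils.graphs_equal(pin.graph, g)

    def test_zero_mapped_seeds_is_an_error(self):
        g = nx.Graph([("A", "B")])
        with pytest.raises(ValueError, match="seed"):
            net.build_pin(["ZZZ"], g)

    def test_matches_brute_force_construction(self):
        g, _ = simulate_interactome(200, 2, seed=3)
        rng = np.random.default_rng(0)
        seeds = [str(s) for s in rng.choice(sorted(g.nodes), 10, replace=False)]
        pin = net.build_pin(seeds, g)
        # independent construction: neighbors by edge scan, then induced edges
        nodes = set(seeds)
        for a, b in g.edges():
            if a in seeds or b in seeds:
                nodes.update((a, b))
        nodes = {n for n in nodes if n in set(seeds)
                 or any((n, s) in g.edges() or (s, n) in g.edges() for s in seeds)}
        edges = {frozenset((a, b)) for a, b in g.edges() if a in nodes and b in nodes}
        assert set(pin.graph.nodes) == nodes
        assert {frozenset(e) for e in pin.graph.edges()} == edges
        # invariant: every non-seed node touches a seed
        for n in pin.graph.nodes:
            if n not in pin.seeds:
                assert any(nb in pin.seeds for nb in pin.graph.neighbors(n))


class TestMappedFraction:
    def test_printed_cohort_arithmetic(self):
        g = nx.empty_graph(0)
        g.add_nodes_from(f"M{i}" for i in range(168))
        seeds = [f"M{i}" for i in range(168)] + [f"U{i}" for i in range(80)]
        n_mapped, n_total, percent = net.mapped_seed_fraction(seeds, g)
        assert (n_mapped, n_total, percent) == (168, 248, 68)

    def test_zero_mapped(self):
        g = nx.Graph([("A", "B")])
        assert net.mapped_seed_fraction(["X"] * 3 + ["Y"], g)[:2] == (0, 2)

    def test_rounding(self):
        g = nx.empty_graph(0)
        g.add_nodes_from(f"M{i}" for i in range(7))
        assert net.mapped_seed_fraction([f"M{i}" for i in range(7)] + ["U0"], g)[2] == 88

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ValueError):
            net.mapped_seed_fraction([], nx.Graph([("A", "B")]))


class TestTopologySummary:
    def test_complete_graph(self):
        pin = net.build_pin(list("ABCD"), nx.complete_graph(["A", "B", "C", "D"]))
        s = net.topology_summary(pin)
        assert s.density == pytest.approx(1.0)
        assert s.aspl == pytest.approx(1.0)

    def test_path_graph_closed_form(self):
        g = nx.path_graph(["A", "B", "C", "D"])
        s = net.topology_summary(net.build_pin(list("ABCD"), g))
        assert s.density == pytest.approx(0.5)
        assert s.aspl == pytest.approx(10 / 6)
        assert s.path_lengths == Counter({1: 3, 2: 2, 3: 1})

    def test_aspl_matches_floyd_warshall_oracle(self):
        g, _ = simulate_interactome(50, 2, seed=9)
        s = net.topology_summary(g)
        nodes = sorted(g.nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        big = 1e9
        d = np.full((50, 50), big)
        np.fill_diagonal(d, 0)
        for a, b in g.edges():
            d[idx[a], idx[b]] = d[idx[b], idx[a]] = 1
        for k in range(50):
            d = np.minimum(d, d[:, [k]] + d[[k], :])
        finite = d[np.triu_indices(50, k=1)]
        finite = finite[finite < big]
        assert s.aspl == pytest.approx(finite.mean())
        assert s.density == pytest.approx(2 * g.number_of_edges() / (50 * 49))

    def test_disconnected_graph_uses_largest_component(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("X", "Y")])
        s = net.topology_summary(g)
        assert s.n_components == 2
        assert s.aspl == pytest.approx((1 + 1 + 2) / 3)
        all_finite = net.topology_summary(g, aspl_mode="all_finite")
        assert all_finite.aspl == pytest.approx((1 + 1 + 2 + 1) / 4)

    def test_single_node_rejected(self):
        g = nx.Graph()
        g.add_node("A")
        with pytest.raises(ValueError):
            net.topology_summary(g)


class TestRandomPINs:
    def test_deterministic_under_seed(self):
        g, _ = simulate_interactome(100, 2, seed=5)
        e1 = net.sample_random_pins(g, 8, 5, rng_seed=3)
        e2 = net.sample_random_pins(g, 8, 5, rng_seed=3)
        assert [sorted(p.seeds) for p in e1] == [sorted(p.seeds) for p in e2]

    def test_all_nodes_reproduces_interactome(self):
        g, _ = simulate_interactome(30, 2, seed=5)
        (pin,) = net.sample_random_pins(g, 30, 1, rng_seed=0)
        assert nx.utils.graphs_equal(pin.graph, g)

    def test_too_many_seeds_rejected(self):
        g, _ = simulate_interactome(20, 2, seed=0)
        with pytest.raises(ValueError):
            net.sample_random_pins(g, 21, 1)

    def test_ensemble_mean_density_stable_against_larger_reference(self):
        g = nx.gnp_random_graph(150, 0.04, seed=1)
        g = nx.relabel_nodes(g, {n: f"N{n}" for n in g.nodes})
        small = net.sample_random_pins(g, 10, 30, rng_seed=2)
        big = net.sample_random_pins(g, 10, 300, rng_seed=7)
        mean = lambda ens: np.mean([net.topology_summary(p).density for p in ens])
        assert mean(small) == pytest.approx(mean(big), rel=0.15)


class TestKS:
    def test_identical_samples(self):
        assert net.ks_two_sample([1, 2, 3], [1, 2, 3])[0] == 0.0

    def test_disjoint_supports(self):
        d, p = net.ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0

    def test_matches_grid_oracle_and_scipy(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(0.7, 1.3, size=40)
        d, p = net.ks_two_sample(x, y)
        grid = np.concatenate([x, y])
        oracle = max(
            abs((x <= v).mean() - (y <= v).mean()) for v in grid
        )
        assert d == pytest.approx(oracle)
        ref = stats.ks_2samp(x, y, method="asymp")
        assert d == pytest.approx(ref.statistic)
        # p-values differ by finite-size corrections to the asymptotic law
        assert p == pytest.approx(ref.pvalue, rel=0.35)

    def test_counter_input_equals_expanded_input(self):
        cx, cy = Counter({1: 5, 2: 3}), Counter({1: 2, 3: 6})
        x = [1] * 5 + [2] * 3
        y = [1] * 2 + [3] * 6
        assert net.ks_two_sample(cx, cy) == net.ks_two_sample(x, y)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            net.ks_two_sample([], [1.0])


class TestCompareTopology:
    def test_degenerate_single_replicate_add_one_rule(self):
        g, _ = simulate_interactome(60, 2, seed=6)
        pin = net.build_pin(sorted(g.nodes)[:5], g)
        comp = net.compare_topology(pin, g, replicates=1, rng_seed=0)
        assert comp.empirical_p_density in (0.5, 1.0)
        assert comp.empirical_p_aspl in (0.5, 1.0)

    def test_planted_module_is_detected(self):
        """A dense module among the seeds shows shorter-than-random paths and
        an overall rejection; scalar density alone is size-confounded (see
        docs) so only the combined verdict is asserted for it."""
        rng = np.random.default_rng(0)
        members = [f"GENE{i}" for i in rng.choice(500, 25, replace=False)]
        g, truth = simulate_interactome(500, 2, planted_module=(members, 0.8), seed=13)
        pin = net.build_pin(truth.module_nodes, g)
        comp = net.compare_topology(pin, g, replicates=200, rng_seed=1)
        assert comp.empirical_p_aspl <= 0.05
        assert 0.0 <= comp.ks_paths[0] <= 1.0 and 0.0 <= comp.ks_degree[0] <= 1.0
        assert comp.rejects(0.05)

    def test_pin_invariants_on_random_fixtures(self):
        g, _ = simulate_interactome(150, 2, seed=8)
        for pin in net.sample_random_pins(g, 12, 5, rng_seed=4):
            s = net.topology_summary(pin)
            assert 0.0 <= s.density <= 1.0
            assert s.aspl >= 1.0
            induced = g.subgraph(pin.graph.nodes)
            assert {frozenset(e) for e in pin.graph.edges()} == {
                frozenset(e) for e in induced.edges()
            }
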