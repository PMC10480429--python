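"""Graph metrics against closed forms and brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

import rsnhubs as rh
from rsnhubs.containers import MetricCurve
from rsnhubs.metrics import curve_from_weights, default_t_grid

from conftest import complete_graph, graph_from_edges, random_graph


class TestGlobalEfficiency:
    def test_complete_graph(self):
        assert rh.global_efficiency(complete_graph(4)) == pytest.approx(1.0)

    def test_path3(self, path3):
        # (1/6) * (1 + 1 + 1 + 1 + 1/2 + 1/2)
        assert rh.global_efficiency(path3) == pytest.approx(5 / 6, abs=1e-12)

    def test_isolated_node_contributes_zero(self):
        k3 = graph_from_edges(4, [(0, 1), (0, 2), (1, 2)])
        assert rh.global_efficiency(k3) < rh.global_efficiency(complete_graph(3))
        assert rh.global_efficiency(k3) == pytest.approx(6 / 12, abs=1e-12)

    def test_weighted_uses_inverse_weight_lengths(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)], weights=[2.0, 2.0])
        # lengths 0.5 each: d(0,1)=0.5, d(0,2)=1.0 -> E = (2+2+1)/6... pairs
        # ordered: (0,1)=2, (1,0)=2, (1,2)=2, (2,1)=2, (0,2)=1, (2,0)=1
        assert rh.global_efficiency(g, weighted=True) == pytest.approx(10 / 6, abs=1e-12)


def _exhaustive_best_q(g) -> float:
    """Literal maximum of Q over every partition (n <= 8 only)."""
    n = g.n_nodes
    a = g.adjacency
    two_m = a.sum()

    def q_of(member):
        q = 0.0
        for u in set(member):
            in_u = np.array([m == u for m in member])
            e_uu = a[np.ix_(in_u, in_u)].sum() / two_m
            a_u = a[in_u, :].sum() / two_m
            q += e_uu - a_u**2
        return q

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1 :]
            yield [[first]] + part

    best = -np.inf
    for part in partitions(list(range(n))):
        member = [0] * n
        for u, block in enumerate(part):
            for v in block:
                member[v] = u
        best = max(best, q_of(member))
    return best


class TestModularity:
    def test_two_disconnected_k4(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i + 4, j + 4) for i, j in edges[:6]]
        g = graph_from_edges(8, edges)
        q, part = rh.modularity_spectral(g)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert sorted(sorted(p) for p in map(list, part)) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_complete_graph_single_community(self):
        q, part = rh.modularity_spectral(complete_graph(5))
        assert q == pytest.approx(0.0, abs=1e-12)
        assert len(part) == 1

    def test_matches_exhaustive_oracle_on_block_fixtures(self):
        fixtures = [
            graph_from_edges(6, [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]),
            graph_from_edges(7, [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3), (5, 6), (4, 6)]),
            graph_from_edges(8, [(0, 1), (1, 2), (2, 3), (0, 3), (4, 5), (5, 6), (6, 7), (4, 7), (0, 4)]),
        ]
        for g in fixtures:
            q, _ = rh.modularity_spectral(g)
            assert q >= 0.0
            assert q == pytest.approx(_exhaustive_best_q(g), abs=1e-9)

    def test_agrees_with_networkx_q(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            g = random_graph(12, 0.3, rng)
            if g.n_edges == 0:
                continue
            _, part = rh.modularity_spectral(g)
            q_mine = rh.modularity_value(g, part)
            q_nx = nx.algorithms.community.modularity(
                nx.from_numpy_array(g.adjacency), [set(p) for p in part]
            )
            assert q_mine == pytest.approx(q_nx, abs=1e-10)

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            rh.modularity_spectral(graph_from_edges(3, []))


class TestTransitivity:
    @pytest.mark.parametrize(
        "edges,n,expected",
        [
            ([(0, 1), (1, 2), (0, 2)], 3, 1.0),  # triangle
            ([(0, 1), (1, 2)], 3, 0.0),  # path, no triangles
            ([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)], 4, 0.75),  # K4 minus an edge
        ],
    )
    def test_closed_forms(self, edges, n, expected):
        assert rh.transitivity(graph_from_edges(n, edges)) == pytest.approx(expected)

    def test_no_triples_returns_zero(self):
        assert rh.transitivity(graph_from_edges(4, [(0, 1)])) == 0.0


class TestCentrality:
    def test_star_center(self, star5):
        bet = rh.centrality(star5, "betweenness")
        clo = rh.centrality(star5, "closeness")
        assert bet[0] == pytest.approx(1.0)
        assert bet[1:] == pytest.approx(0.0)
        assert clo[0] == pytest.approx(1.0)

    def test_path3_betweenness(self, path3):
        bet = rh.centrality(path3, "betweenness")
        assert bet[1] == pytest.approx(1.0)
        assert bet[0] == pytest.approx(0.0)

    def test_cycle_eigenvector_uniform(self):
        n = 7
        g = graph_from_edges(n, [(i, (i + 1) % n) for i in range(n)])
        ev = rh.centrality(g, "eigenvector")
        assert ev == pytest.approx(np.ones(n))

    def test_degree_is_binarized(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)], weights=[5.0, 2.0])
        assert rh.centrality(g, "degree").tolist() == [1, 2, 1]

    def test_eigenvector_edgeless_errors(self):
        with pytest.raises(ValueError):
            rh.centrality(graph_from_edges(3, []), "eigenvector")

    def test_betweenness_matches_exhaustive_oracle(self):
        """Literal Eq-style oracle: enumerate all shortest paths, n <= 7."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 60:
            n = int(rng.integers(3, 8))
            g = random_graph(n, 0.5, rng)
            G = nx.from_numpy_array(g.adjacency)
            if not nx.is_connected(G):
                continue
            bet = rh.centrality(g, "betweenness")
            oracle = np.zeros(n)
            for h, j in itertools.permutations(range(n), 2):
                paths = list(nx.all_shortest_paths(G, h, j))
                for i in range(n):
                    if i in (h, j):
                        continue
                    thru = sum(1 for pth in paths if i in pth)
                    oracle[i] += thru / len(paths)
            oracle /= (n - 1) * (n - 2)
            np.testing.assert_allclose(bet, oracle, atol=1e-12)
            checked += 1


class TestHits:
    def test_star_center_max(self, star5):
        h = rh.hits_scores(star5)
        assert np.argmax(h) == 0

    def test_regular_graph_uniform(self):
        n = 6
        g = graph_from_edges(n, [(i, (i + 1) % n) for i in range(n)])  # 2-regular
        h = rh.hits_scores(g)
        np.testing.assert_allclose(h, h[0], atol=1e-8)

    def test_path3_ranking(self, path3):
        h = rh.hits_scores(path3)
        assert h[1] > h[0]
        assert h[0] == pytest.approx(h[2], abs=1e-8)

    def test_edgeless_errors(self):
        with pytest.raises(ValueError):
            rh.hits_scores(graph_from_edges(2, []))


class TestGiantComponent:
    def test_sizes(self):
        g = graph_from_edges(8, [(0, 1), (1, 2), (2, 3), (3, 4), (5, 6), (6, 7)])
        size, members = rh.giant_component(g)
        assert size == 5
        assert members == frozenset({0, 1, 2, 3, 4})

    def test_edgeless_singletons(self):
        assert rh.giant_component(graph_from_edges(5, []))[0] == 1

    def test_tie_break_smallest_index(self):
        g = graph_from_edges(6, [(1, 2), (0, 4), (3, 5)])
        _, members = rh.giant_component(g)
        assert members == frozenset({0, 4})

    def test_monotone_under_edge_removal(self):
        rng = np.random.default_rng(1)
        g = random_graph(15, 0.2, rng)
        size0 = rh.giant_component(g)[0]
        for i, j, _ in g.edge_list():
            adj = g.adjacency.copy()
            adj[i, j] = adj[j, i] = 0.0
            assert rh.giant_component(rh.ThresholdedGraph(adj, g.node_labels))[0] <= size0


class TestModuleComposition:
    def test_two_cliques_natural_partition(self):
        edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]
        g = graph_from_edges(6, edges)
        assert rh.module_composition(g, [{0, 1, 2}, {3, 4, 5}]) == (2, 1.0)

    def test_split_clique(self):
        g = complete_graph(4)
        n_mod, intra = rh.module_composition(g, [{0, 1}, {2, 3}])
        assert n_mod == 2
        assert intra == pytest.approx(2 / 6)

    def test_single_community(self):
        g = complete_graph(4)
        assert rh.module_composition(g, [{0, 1, 2, 3}]) == (1, 1.0)

    def test_partition_must_cover(self):
        with pytest.raises(ValueError):
            rh.module_composition(complete_graph(3), [{0, 1}])


class TestMetricCurve:
    def test_trapezoid_rectangle_and_triangle(self):
        taus = default_t_grid()
        assert MetricCurve("m", taus, np.ones(10)).auc == pytest.approx(1.8)
        assert MetricCurve("m", taus, np.linspace(1, 0, 10)).auc == pytest.approx(0.9)

    def test_giant_curve_non_increasing(self, null_diff):
        curve = rh.metric_curve(null_diff, "giant_component")
        assert (np.diff(curve.values) <= 1e-12).all()

    def test_degenerate_convention_flagged(self):
        w = np.zeros((5, 5))  # nothing survives any threshold
        for metric, expect in [
            ("giant_component", 1.0), ("global_efficiency", 0.0),
            ("modularity", 0.0), ("transitivity", 0.0),
        ]:
            c = curve_from_weights(w, metric, default_t_grid())
            assert (c.values == expect).all()
            assert c.flagged.all()

    def test_relabeling_invariance(self, null_diff):
        """Metric values are invariant to a node permutation."""
        rng = np.random.default_rng(8)
        perm = rng.permutation(null_diff.n_regions)
        t_perm = null_diff.t[np.ix_(perm, perm)]
        for metric in ("giant_component", "global_efficiency", "transitivity"):
            c1 = curve_from_weights(np.abs(null_diff.t), metric, default_t_grid()[:4])
            c2 = curve_from_weights(np.abs(t_perm), metric, default_t_grid()[:4])
            np.testing.assert_allclose(c1.values, c2.values, atol=1e-10)


class TestSmallWorld:
    def _fc_from_adj(self, adj):
        z = adj.astype(float)
        return rh.FCMatrix(z=z, region_labels=[f"R{i}" for i in range(adj.shape[0])])

    def test_complete_graph_c1_l1(self):
        n = 20
        adj = np.ones((n, n)) - np.eye(n)
        res = rh.small_world(self._fc_from_adj(adj), np.array([0.5]))
        k = n - 1
        assert res.lam[0] == pytest.approx(1.0 / (np.log(n) / np.log(k)))
        assert res.gamma[0] == pytest.approx(1.0 / (k / n))

    def test_ring_lattice_high_gamma(self):
        G = nx.watts_strogatz_graph(100, 6, 0.0, seed=1)  # pure ring lattice
        adj = nx.to_numpy_array(G)
        res = rh.small_world(self._fc_from_adj(adj), np.array([0.5]))
        assert res.gamma[0] > 2.0
        assert res.sigma[0] > 1.5

    def test_er_self_consistency(self):
        sigmas = []
        for seed in range(20):
            G = nx.gnp_random_graph(100, 8 / 99, seed=seed)
            if min(dict(G.degree()).values()) == 0:
                continue
            adj = nx.to_numpy_array(G)
            res = rh.small_world(self._fc_from_adj(adj), np.array([0.5]))
            sigmas.append(res.sigma[0])
        assert len(sigmas) >= 15
        assert all(0.7 <= s <= 1.3 for s in sigmas)

    def test_isolated_node_at_max_threshold_errors(self):
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[1, 0] = 1.0
        with pytest.raises(ValueError, match="isolated"):
            rh.small_world(self._fc_from_adj(adj), np.array([0.5]))


def test_metrics_in_valid_ranges(null_diff):
    """Efficiency and transitivity in [0,1]; Q in [-0.5, 1]."""
    for tau in (2.0, 2.6):
        g = rh.threshold_graph(null_diff, "t_score", tau)
        if g.n_edges == 0:
            continue
        assert 0.0 <= rh.global_efficiency(g) <= 1.0
        assert 0.0 <= rh.transitivity(g) <= 1.0
        q, _ = rh.modularity_spectral(g)
        assert -0.5 <= q <= 1.0
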