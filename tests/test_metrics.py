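"""Structural metrics against published values and independent oracles."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.sparse.csgraph import floyd_warshall

from hcmnet import (
    Network,
    UNREACHABLE,
    all_pairs_distances,
    betweenness_centrality,
    closeness_centrality,
    degree_centrality,
    degree_density,
    degree_vector,
    eigenvector_centrality,
    generate_er,
    k_shell,
    network_density,
)
from hcmnet.metrics import ConvergenceError

from conftest import FIXTURE_DISTANCES


def _fw_oracle(net):
    """Independent all-pairs distances via scipy's Floyd-Warshall."""
    a = nx.to_numpy_array(net.to_networkx(), nodelist=net.labels)
    d = floyd_warshall(a, unweighted=True)
    d[np.isinf(d)] = UNREACHABLE
    return d.astype(int)


def _kshell_pruning_oracle(net):
    """Direct simulation of recursive deletion by increasing degree."""
    g = net.to_networkx()
    shell = {}
    k = 0
    while g:
        k = max(k, min(dict(g.degree).values()))
        while True:
            peel = [n for n, d in g.degree if d <= k]
            if not peel:
                break
            for n in peel:
                shell[n] = k
            g.remove_nodes_from(peel)
    return shell


def _betweenness_enumeration_oracle(net):
    """Pair-normalized betweenness by brute-force shortest-path enumeration."""
    g = net.to_networkx()
    n = net.N
    acc = dict.fromkeys(net.labels, 0.0)
    labels = list(net.labels)
    for i, s in enumerate(labels):
        for t in labels[i + 1:]:
            if not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            for v in labels:
                if v in (s, t):
                    continue
                acc[v] += sum(v in p for p in paths) / len(paths)
    norm = 2.0 / ((n - 1) * (n - 2))
    return {v: acc[v] * norm for v in acc}


class TestDegree:
    def test_fixture_degrees(self, fixture_net):
        d = degree_vector(fixture_net)
        assert d["v1"] == 4 and d["v5"] == 1
        assert sum(d.values()) == 2 * fixture_net.M

    def test_isolated_node(self):
        net = Network([("a", "b")], nodes=["c"])
        assert degree_vector(net)["c"] == 0


class TestDegreeCentrality:
    def test_fixture_v1(self, fixture_net):
        assert degree_centrality(fixture_net)["v1"] == pytest.approx(0.4)

    def test_star_center_and_isolate(self):
        star = Network([("c", f"l{i}") for i in range(4)], nodes=["iso"])
        dc = degree_centrality(star)
        assert dc["c"] == pytest.approx(4 / 5)
        assert dc["iso"] == 0.0

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            degree_centrality(Network(nodes=["a"]))


class TestEigenvectorCentrality:
    def test_triangle_symmetry(self):
        k3 = Network([("a", "b"), ("b", "c"), ("a", "c")])
        ec = eigenvector_centrality(k3)
        for v in "abc":
            assert ec[v] == pytest.approx(1 / math.sqrt(3), abs=1e-9)

    def test_matches_networkx_on_random_graph(self):
        net = generate_er(40, 0.15, seed=7)
        ours = eigenvector_centrality(net)
        ref = nx.eigenvector_centrality_numpy(net.to_networkx())
        for v in net.labels:
            assert ours[v] == pytest.approx(ref[v], abs=1e-6)

    def test_eigenpair_residual_and_unit_norm(self, fixture_net):
        ec = eigenvector_centrality(fixture_net, tol=1e-12)
        x = ec.values_array(fixture_net.labels)
        a = nx.to_numpy_array(fixture_net.to_networkx(), nodelist=fixture_net.labels)
        lam = x @ a @ x
        assert np.linalg.norm(x) == pytest.approx(1.0, abs=1e-10)
        assert np.max(np.abs(a @ x - lam * x)) < 1e-8
        assert np.all(x >= 0)

    def test_bipartite_graph_converges(self):
        # path graphs oscillate under plain power iteration; the shift fixes it
        path = Network([("a", "b"), ("b", "c"), ("c", "d")])
        ec = eigenvector_centrality(path)
        assert ec["b"] == pytest.approx(ec["c"], abs=1e-8)

    def test_edgeless_rejected_and_convergence_error(self, fixture_net):
        with pytest.raises(ValueError):
            eigenvector_centrality(Network(nodes=["a", "b"]))
        with pytest.raises(ConvergenceError, match="residual"):
            eigenvector_centrality(fixture_net, tol=1e-15, max_iter=3)


class TestDistances:
    def test_fixture_matches_published_block(self, fixture_net):
        dist = all_pairs_distances(fixture_net)
        for u, row in FIXTURE_DISTANCES.items():
            for v, expected in zip(fixture_net.labels, row):
                got = dist.get(u, v)
                assert got == expected, (u, v, got, expected)

    def test_unreachable_marker(self):
        net = Network([("a", "b"), ("c", "d")])
        dist = all_pairs_distances(net)
        assert dist.get("a", "c") == UNREACHABLE
        assert not dist.is_reachable("a", "c")
        assert dist.get("a", "a") == 0

    @pytest.mark.parametrize("n,p,seed", [(10, 0.2, 0), (30, 0.1, 1), (50, 0.05, 2)])
    def test_matches_floyd_warshall_oracle(self, n, p, seed):
        net = generate_er(n, p, seed)
        assert np.array_equal(all_pairs_distances(net).hops, _fw_oracle(net))


class TestCloseness:
    def test_fixture_values(self, fixture_net):
        cc = closeness_centrality(fixture_net)
        assert cc["v1"] == pytest.approx(10 / 18, abs=1e-5)
        assert cc["v5"] == pytest.approx(0.32258, abs=1e-5)

    def test_path_center(self):
        assert closeness_centrality(Network([("a", "b"), ("b", "c")]))["b"] == 1.0

    def test_disconnected_uses_component_size(self):
        net = Network([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y")], nodes=["iso"])
        cc = closeness_centrality(net)
        assert cc["a"] == 1.0  # triangle: (3-1)/2
        assert cc["x"] == 1.0  # pair: (2-1)/1
        assert cc["iso"] == 0.0


class TestNetworkDensity:
    def test_fixture(self, fixture_net):
        assert network_density(fixture_net) == pytest.approx(0.29091, abs=1e-5)

    def test_extremes(self):
        k3 = Network([("a", "b"), ("b", "c"), ("a", "c")])
        assert network_density(k3) == 1.0
        assert network_density(Network(nodes=["a", "b"])) == 0.0

    def test_monotone_under_edge_addition(self):
        net = Network([("a", "b")], nodes=["c"])
        denser = Network([("a", "b"), ("b", "c")])
        assert network_density(denser) > network_density(net)


class TestDegreeDensity:
    @pytest.mark.parametrize("deg,dist,expected", [
        (4, 1, 1.27324),  # toward v1 from its degree-4 neighbor
        (4, 2, 0.31831),  # toward v1 from a degree-4 node two hops away
        (0, 3, 0.0),
    ])
    def test_quadratic_published_values(self, deg, dist, expected):
        assert degree_density(deg, dist, "quadratic") == pytest.approx(expected, abs=1e-5)

    def test_modes_coincide_at_distance_one(self):
        assert degree_density(3, 1, "quadratic") == pytest.approx(
            degree_density(3, 1, "exponential"))

    @pytest.mark.parametrize("mode", ["quadratic", "exponential"])
    def test_strictly_monotone(self, mode):
        in_dist = [degree_density(3, r, mode) for r in range(1, 6)]
        assert all(a > b for a, b in zip(in_dist, in_dist[1:]))
        in_deg = [degree_density(d, 2, mode) for d in range(1, 6)]
        assert all(a < b for a, b in zip(in_deg, in_deg[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            degree_density(3, 0)
        with pytest.raises(ValueError):
            degree_density(-1, 2)
        with pytest.raises(ValueError):
            degree_density(3, 1, mode="cubic")


class TestKShell:
    def test_star_and_clique(self):
        star = Network([("c", f"l{i}") for i in range(5)])
        assert set(k_shell(star).values()) == {1.0}
        k4 = Network([(a, b) for a in "abcd" for b in "abcd" if a < b])
        assert set(k_shell(k4).values()) == {3.0}

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_pruning_oracle(self, fixture_net, seed):
        for net in (fixture_net, generate_er(30, 0.15, seed)):
            ks = k_shell(net)
            oracle = _kshell_pruning_oracle(net)
            assert {v: ks[v] for v in net.labels} == pytest.approx(oracle)
            assert all(ks[v] <= net.degree(v) for v in net.labels)


class TestBetweenness:
    def test_path_midpoint(self):
        bc = betweenness_centrality(Network([("a", "b"), ("b", "c")]))
        assert bc["b"] == pytest.approx(1.0)
        assert bc["a"] == 0.0

    def test_cycle_symmetry(self):
        c4 = Network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        assert len(set(betweenness_centrality(c4).values())) == 1

    def test_fixture_matches_enumeration_oracle(self, fixture_net):
        bc = betweenness_centrality(fixture_net)
        oracle = _betweenness_enumeration_oracle(fixture_net)
        for v in fixture_net.labels:
            assert bc[v] == pytest.approx(oracle[v], abs=1e-12)
        assert bc.ranked()[0] == "v1"


@settings(max_examples=20, deadline=None, derandomize=True)
@given(n=st.integers(3, 25), p=st.floats(0.1, 0.9), seed=st.integers(0, 500))
def test_density_invariant_under_relabelling(n, p, seed):
    net = generate_er(n, p, seed)
    relabelled = Network(
        ((f"x{u}", f"x{v}") for u, v in net.edges),
        nodes=(f"x{l}" for l in net.labels),
    )
    assert network_density(net) == pytest.approx(network_density(relabelled))
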