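import itertools

import networkx as nx
import numpy as np
import pytest

from ggmbench import (
    NetworkTopology,
    average_path_length,
    betweenness,
    clustering_and_triangles,
    components,
    degree_and_strength,
    generate_random,
    small_worldness,
    topology_metrics,
)
from ggmbench.selection import BinaryNetwork


def _net(n, edges):
    return BinaryNetwork(n, frozenset(edges))


def _random_net(n, seed, p=0.15):
    rng = np.random.default_rng(seed)
    edges = {
        (i, j)
        for i, j in itertools.combinations(range(n), 2)
        if rng.random() < p
    }
    return _net(n, edges)


# ---------------------------------------------------------------- brute force

def _bfs_distances(adj, start, n):
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for v in frontier:
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def _brute_apl(net):
    adj = {i: set() for i in range(net.n_nodes)}
    for i, j in net.edges:
        adj[i].add(j)
        adj[j].add(i)
    dists = []
    for s in range(net.n_nodes):
        d = _bfs_distances(adj, s, net.n_nodes)
        dists.extend(v for k, v in d.items() if k != s)
    if not dists:
        return float("nan")
    return sum(dists) / len(dists)


def _brute_triangles_and_transitivity(net):
    es = set(net.edges)
    n = net.n_nodes
    triangles = sum(
        1
        for a, b, c in itertools.combinations(range(n), 3)
        if (a, b) in es and (b, c) in es and (a, c) in es
    )
    deg = np.zeros(n, dtype=int)
    for i, j in es:
        deg[i] += 1
        deg[j] += 1
    triples = int((deg * (deg - 1) // 2).sum())
    transitivity = 3 * triangles / triples if triples else 0.0
    return transitivity, triangles


def _brute_betweenness(net):
    """Brandes-free path-enumeration betweenness for tiny graphs."""
    n = net.n_nodes
    adj = {i: set() for i in range(n)}
    for i, j in net.edges:
        adj[i].add(j)
        adj[j].add(i)
    bet = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        # enumerate all shortest s-t paths by BFS layering
        dist = _bfs_distances(adj, s, n)
        if t not in dist:
            continue
        paths = []
        stack = [[t]]
        while stack:
            path = stack.pop()
            head = path[-1]
            if head == s:
                paths.append(path)
                continue
            for w in adj[head]:
                if w in dist and dist[w] == dist[head] - 1:
                    stack.append(path + [w])
        for path in paths:
            for v in path[1:-1]:
                bet[v] += 1.0 / len(paths)
    return bet


# -------------------------------------------------------------------- tests

class TestAveragePathLength:
    def test_path_graph_four_nodes(self):
        net = _net(4, {(0, 1), (1, 2), (2, 3)})
        assert average_path_length(net) == pytest.approx(5.0 / 3.0)

    def test_complete_graph(self):
        net = _net(5, set(itertools.combinations(range(5), 2)))
        assert average_path_length(net) == 1.0

    def test_reachable_pairs_only(self):
        net = _net(4, {(0, 1), (2, 3)})
        assert average_path_length(net) == 1.0

    def test_no_edges_raises(self):
        with pytest.raises(ValueError):
            average_path_length(_net(4, set()))

    def test_matches_brute_force(self):
        for s in range(100):
            net = _random_net(int(np.random.default_rng(s).integers(5, 40)), s)
            if not net.edges:
                continue
            assert average_path_length(net) == pytest.approx(_brute_apl(net))


class TestClusteringAndTriangles:
    def test_tree_no_triangles(self):
        net = _net(9, {(0, i) for i in range(1, 9)})
        c, t, _ = clustering_and_triangles(net)
        assert (c, t) == (0.0, 0)

    def test_complete_graph_nine_nodes(self):
        net = _net(9, set(itertools.combinations(range(9), 2)))
        c, t, local = clustering_and_triangles(net)
        assert c == 1.0
        assert t == 84  # C(9,3)
        assert np.allclose(local, 1.0)

    def test_single_triangle(self):
        net = _net(3, {(0, 1), (1, 2), (0, 2)})
        c, t, local = clustering_and_triangles(net)
        assert c == 1.0 and t == 1
        assert np.allclose(local, [1, 1, 1])

    def test_local_nan_below_degree_two(self):
        net = _net(3, {(0, 1)})
        _, _, local = clustering_and_triangles(net)
        assert np.all(np.isnan(local))

    def test_matches_brute_force(self):
        for s in range(100):
            net = _random_net(int(np.random.default_rng(s).integers(4, 40)), s + 1000)
            c, t, _ = clustering_and_triangles(net)
            bc, bt = _brute_triangles_and_transitivity(net)
            assert t == bt
            assert c == pytest.approx(bc)

    def test_er_clustering_near_density(self):
        cs, dens = [], []
        for s in range(8):
            g = generate_random(300, count=2500, seed=s)
            cs.append(clustering_and_triangles(g)[0])
            dens.append(g.density)
        assert np.mean(cs) == pytest.approx(np.mean(dens), abs=0.01)


class TestComponents:
    def test_connected(self):
        net = _net(4, {(0, 1), (1, 2), (2, 3)})
        assert components(net) == (1, 4)

    def test_two_disjoint_edges(self):
        assert components(_net(4, {(0, 1), (2, 3)})) == (2, 2)

    def test_empty_network(self):
        assert components(_net(5, set())) == (5, 1)

    def test_matches_networkx(self):
        for s in range(50):
            net = _random_net(20, s, p=0.06)
            G = nx.Graph(list(net.edges))
            G.add_nodes_from(range(net.n_nodes))
            comps = list(nx.connected_components(G))
            assert components(net) == (len(comps), max(len(c) for c in comps))


class TestBetweenness:
    def test_star(self):
        net = _net(4, {(0, 1), (0, 2), (0, 3)})
        per_node, avg = betweenness(net)
        assert np.allclose(per_node, [3, 0, 0, 0])
        assert avg == pytest.approx(0.75)

    def test_path_three_nodes(self):
        per_node, _ = betweenness(_net(3, {(0, 1), (1, 2)}))
        assert np.allclose(per_node, [0, 1, 0])

    def test_complete_graph_zero(self):
        net = _net(5, set(itertools.combinations(range(5), 2)))
        per_node, avg = betweenness(net)
        assert np.allclose(per_node, 0.0)

    def test_matches_path_enumeration_oracle(self):
        for s in range(30):
            net = _random_net(12, s + 7, p=0.25)
            per_node, _ = betweenness(net)
            assert np.allclose(per_node, _brute_betweenness(net), atol=1e-9)

    def test_matches_networkx_larger(self):
        for s in range(100):
            net = _random_net(int(np.random.default_rng(s).integers(5, 40)), s + 31)
            G = nx.Graph(list(net.edges))
            G.add_nodes_from(range(net.n_nodes))
            expected = nx.betweenness_centrality(G, normalized=False)
            per_node, _ = betweenness(net)
            # networkx counts ordered pairs twice for undirected: it doesn't —
            # both count each unordered pair once
            assert np.allclose(per_node, [expected[i] for i in range(net.n_nodes)])


class TestDegreeAndStrength:
    def test_star_center(self):
        deg, _ = degree_and_strength(_net(4, {(0, 1), (0, 2), (0, 3)}))
        assert deg[0] == 3

    def test_unit_weights_strength_equals_degree(self):
        net = _net(3, {(0, 1), (1, 2)})
        W = np.ones((3, 3))
        deg, strength = degree_and_strength(net, W)
        assert np.allclose(strength, deg)

    def test_absolute_value_convention(self):
        net = _net(2, {(0, 1)})
        W = np.array([[1.0, -0.5], [-0.5, 1.0]])
        _, strength = degree_and_strength(net, W)
        assert np.allclose(strength, [0.5, 0.5])

    def test_degree_sum_invariant(self):
        for s in range(20):
            net = _random_net(15, s)
            deg, _ = degree_and_strength(net)
            assert deg.sum() == 2 * net.n_edges


class TestSmallWorldness:
    def test_er_near_one(self):
        vals = [
            small_worldness(
                generate_random(500, count=4000, seed=s), reference_seeds=range(5)
            )
            for s in range(5)
        ]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_self_reference_is_one(self):
        g = generate_random(200, count=1500, seed=0)
        C, _, _ = clustering_and_triangles(g)
        L = average_path_length(g)
        # reference with the graph's own quantities: (C/C)/(L/L) = 1
        class _SelfRef:
            n_nodes, edges = g.n_nodes, g.edges
        assert (C / C) / (L / L) == 1.0

    def test_ring_lattice_above_one(self):
        n = 500
        edges = set()
        for i in range(n):
            for d in (1, 2):
                edges.add(tuple(sorted((i, (i + d) % n))))
        net = _net(n, edges)
        assert small_worldness(net, reference_seeds=range(5)) > 1.0

    def test_analytic_mode_close_to_simulated(self):
        g = generate_random(400, count=3000, seed=1)
        sim = small_worldness(g, reference_seeds=range(5), mode="simulated")
        ana = small_worldness(g, mode="analytic")
        assert sim == pytest.approx(ana, rel=0.25)

    def test_degenerate_reference_raises(self):
        net = _net(4, {(0, 1), (1, 2)})  # references too sparse for triangles
        with pytest.raises(ValueError):
            small_worldness(net, reference_seeds=range(3))


class TestTopologyMetricsVector:
    def test_shape_and_finiteness(self):
        g = generate_random(100, count=600, seed=0)
        v = topology_metrics(g)
        assert v.shape == (6,)
        assert np.all(np.isfinite(v))
        assert np.all(v >= 0)
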