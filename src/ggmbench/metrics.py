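"""Network characteristics.

All functions accept anything graph-like with ``n_nodes`` and ``edges``
attributes (:class:`~ggmbench.topology.NetworkTopology` or
:class:`~ggmbench.selection.BinaryNetwork`).  Heavy lifting is delegated to
igraph; the test suite cross-checks every quantity against brute-force
implementations on small graphs.

Convention notes (they matter for fragmented estimated networks):

* average path length is the mean geodesic distance over ordered *reachable*
  pairs only;
* betweenness credits each unordered pair of endpoints once, with fractional
  credit when geodesics tie;
* local transitivity is undefined (NaN) for nodes of degree < 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import igraph as ig
import numpy as np
import scipy.sparse as sp


def _as_igraph(net) -> ig.Graph:
    return ig.Graph(net.n_nodes, [tuple(e) for e in sorted(net.edges)])


def _adjacency(net) -> sp.csr_matrix:
    n = net.n_nodes
    if not net.edges:
        return sp.csr_matrix((n, n))
    ea = np.array(sorted(net.edges), dtype=np.int64)
    data = np.ones(2 * len(ea))
    rows = np.concatenate([ea[:, 0], ea[:, 1]])
    cols = np.concatenate([ea[:, 1], ea[:, 0]])
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def average_path_length(net) -> float:
    """Mean geodesic distance over reachable ordered pairs."""
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not net.edges:
        raise ValueError("no reachable pairs: the graph has no edges")
    g = _as_igraph(net)
    apl = g.average_path_length(directed=False, unconn=True)
    if math.isnan(apl):
        raise ValueError("average path length undefined: no reachable pairs")
    return float(apl)


def clustering_and_triangles(net) -> tuple[float, int, np.ndarray]:
    """(global transitivity, triangle count, per-node local transitivity).

    Global transitivity is 3 x triangles / connected triples (0 when there
    are no triples); local transitivity is NaN for nodes of degree < 2.
    """
    g = _as_igraph(net)
    global_c = float(g.transitivity_undirected(mode="zero"))
    A = _adjacency(net)
    n_triangles = int(round((A @ A).multiply(A).sum() / 6.0))
    local = np.array(g.transitivity_local_undirected(mode="nan"), dtype=float)
    return global_c, n_triangles, local


def components(net) -> tuple[int, int]:
    """(number of connected components incl. isolated nodes, largest size)."""
    g = _as_igraph(net)
    comp = g.connected_components()
    sizes = comp.sizes()
    return len(sizes), int(max(sizes))


def betweenness(net) -> tuple[np.ndarray, float]:
    """Shortest-path betweenness per node, and its average.

    Unweighted geodesics; each unordered endpoint pair contributes once,
    split fractionally across tied geodesics.
    """
    g = _as_igraph(net)
    per_node = np.array(g.betweenness(directed=False), dtype=float)
    return per_node, float(per_node.mean())


def degree_and_strength(net, weights=None) -> tuple[np.ndarray, np.ndarray]:
    """Per-node degree and (if weights given) absolute-weight strength."""
    n = net.n_nodes
    deg = np.zeros(n, dtype=np.int64)
    strength = np.zeros(n, dtype=float)
    W = None
    if weights is not None:
        W = weights.values if hasattr(weights, "values") else np.asarray(weights)
        if W.shape != (n, n):
            raise ValueError("weight matrix shape does not match network")
    for i, j in net.edges:
        deg[i] += 1
        deg[j] += 1
        if W is not None:
            w = abs(W[i, j])
            strength[i] += w
            strength[j] += w
    if W is None:
        strength = deg.astype(float)
    return deg, strength


def small_worldness(
    net,
    reference_seeds=None,
    mode: str = "simulated",
) -> float:
    """Small-worldness index (C / C_rand) / (L / L_rand).

    ``mode="simulated"`` estimates C_rand and L_rand as means over ER graphs
    with identical node and edge counts, one per reference seed (default 10
    seeds).  ``mode="analytic"`` uses C_rand = density and
    L_rand = ln(n)/ln(mean degree).
    """
    from ggmbench.topology import generate_random

    C = clustering_and_triangles(net)[0]
    L = average_path_length(net)
    n, m = net.n_nodes, len(net.edges)
    if mode == "analytic":
        c_rand = 2.0 * m / (n * (n - 1))
        mean_deg = 2.0 * m / n
        if mean_deg <= 1.0:
            raise ValueError("analytic reference undefined for mean degree <= 1")
        l_rand = math.log(n) / math.log(mean_deg)
    elif mode == "simulated":
        if reference_seeds is None:
            reference_seeds = range(10)
        cs, ls = [], []
        for s in reference_seeds:
            ref = generate_random(n, count=m, seed=s)
            cs.append(clustering_and_triangles(ref)[0])
            ls.append(average_path_length(ref))
        c_rand = float(np.mean(cs))
        l_rand = float(np.mean(ls))
    else:
        raise ValueError("mode must be 'simulated' or 'analytic'")
    if c_rand == 0:
        raise ValueError("degenerate reference: C_rand = 0")
    return (C / c_rand) / (L / l_rand)


@dataclass(frozen=True)
class MetricsReport:
    avg_path_length: float
    global_clustering: float
    local_transitivity: np.ndarray
    small_worldness: float
    n_components: int
    largest_component_size: int
    avg_betweenness: float
    betweenness_per_node: np.ndarray
    degree: np.ndarray
    strength: np.ndarray
    n_triangles: int

    def to_dict(self) -> dict:
        return {
            "avg_path_length": self.avg_path_length,
            "global_clustering": self.global_clustering,
            "small_worldness": self.small_worldness,
            "n_components": self.n_components,
            "largest_component_size": self.largest_component_size,
            "avg_betweenness": self.avg_betweenness,
            "n_triangles": self.n_triangles,
            "avg_degree": float(self.degree.mean()),
        }


def metrics_report(
    net,
    weights=None,
    swi_mode: str = "simulated",
    swi_seeds=None,
) -> MetricsReport:
    """All network characteristics in one pass."""
    global_c, n_tri, local = clustering_and_triangles(net)
    apl = average_path_length(net)
    n_comp, largest = components(net)
    per_node_bet, avg_bet = betweenness(net)
    deg, strength = degree_and_strength(net, weights)
    try:
        swi = small_worldness(net, reference_seeds=swi_seeds, mode=swi_mode)
    except ValueError:
        swi = float("nan")
    return MetricsReport(
        avg_path_length=apl,
        global_clustering=global_c,
        local_transitivity=local,
        small_worldness=swi,
        n_components=n_comp,
        largest_component_size=largest,
        avg_betweenness=avg_bet,
        betweenness_per_node=per_node_bet,
        degree=deg,
        strength=strength,
        n_triangles=n_tri,
    )


def topology_metrics(net, swi_mode: str = "analytic", swi_seeds=None) -> np.ndarray:
    """Metrics vector used for representative-topology selection.

    Order: transitivity, average path length, average degree, degree
    variance, average betweenness, small-worldness.
    """
    global_c, _, _ = clustering_and_triangles(net)
    apl = average_path_length(net)
    deg = degree_and_strength(net)[0].astype(float)
    _, avg_bet = betweenness(net)
    swi = small_worldness(net, reference_seeds=swi_seeds, mode=swi_mode)
    return np.array([global_c, apl, deg.mean(), deg.var(ddof=0), avg_bet, swi])
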