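"""Ground-truth network topology generators.

All generators return a :class:`NetworkTopology`: an undirected simple graph
over nodes ``0..n_nodes-1`` stored as a frozenset of ``(i, j)`` pairs with
``i < j``.  Generation is fully determined by an integer seed.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass

import igraph as ig
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

Edge = tuple[int, int]


def _canon(i: int, j: int) -> Edge:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class NetworkTopology:
    """Undirected simple graph serving as ground truth.

    Parameters
    ----------
    n_nodes:
        Number of nodes; node indices run from 0 to ``n_nodes - 1``.
    edges:
        Unordered node-index pairs, canonicalized to ``i < j``.
    labels:
        Optional human-readable node identifiers (1-based names by default
        in serialized output).
    """

    n_nodes: int
    edges: frozenset[Edge]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        for i, j in self.edges:
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"invalid edge ({i}, {j}) for n_nodes={self.n_nodes}")
        if self.labels is not None and len(self.labels) != self.n_nodes:
            raise ValueError("labels must have one entry per node")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def density(self) -> float:
        total = self.n_nodes * (self.n_nodes - 1) // 2
        return self.n_edges / total if total else 0.0

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def edge_array(self) -> np.ndarray:
        """Edges as a sorted (m, 2) integer array; deterministic order."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(sorted(self.edges), dtype=np.int64)

    def adjacency(self, sparse: bool = True):
        """Symmetric 0/1 adjacency matrix."""
        ea = self.edge_array()
        n = self.n_nodes
        data = np.ones(2 * len(ea))
        rows = np.concatenate([ea[:, 0], ea[:, 1]])
        cols = np.concatenate([ea[:, 1], ea[:, 0]])
        mat = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
        return mat if sparse else np.asarray(mat.todense())

    def to_igraph(self) -> ig.Graph:
        return ig.Graph(self.n_nodes, [tuple(e) for e in sorted(self.edges)])


def _decode_pair_index(idx: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map lexicographic upper-triangle indices to (i, j) pairs, i < j."""
    idx = np.asarray(idx, dtype=np.int64)
    b = 2 * n - 1
    i = np.floor((b - np.sqrt(b * b - 8.0 * idx)) / 2.0).astype(np.int64)
    # guard against float rounding at block boundaries
    base = i * (2 * n - i - 1) // 2
    too_big = base > idx
    i[too_big] -= 1
    base = i * (2 * n - i - 1) // 2
    too_small = (i + 1) * (2 * n - i - 2) // 2 <= idx
    i[too_small] += 1
    base = i * (2 * n - i - 1) // 2
    j = idx - base + i + 1
    return i, j


def generate_random(
    n_nodes: int,
    *,
    probability: float | None = None,
    count: int | None = None,
    seed: int = 0,
) -> NetworkTopology:
    """Erdős–Rényi graph: per-edge probability, or exact edge count.

    With ``count``, exactly that many distinct edges are sampled uniformly
    without replacement from the ``n(n-1)/2`` possible pairs.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if (probability is None) == (count is None):
        raise ValueError("specify exactly one of probability or count")
    total = n_nodes * (n_nodes - 1) // 2
    rng = np.random.default_rng(seed)
    if count is not None:
        if not 0 <= count <= total:
            raise ValueError(f"count must be in [0, {total}]")
        chosen = rng.choice(total, size=count, replace=False)
    else:
        if not 0.0 <= probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        mask = rng.random(total) < probability
        chosen = np.flatnonzero(mask)
    ii, jj = _decode_pair_index(chosen, n_nodes)
    edges = frozenset(zip(ii.tolist(), jj.tolist()))
    return NetworkTopology(n_nodes, edges)


def generate_acquaintance(
    n_nodes: int, p_d: float, iterations: int, seed: int = 0
) -> NetworkTopology:
    """Acquaintance ("introduce two neighbors") small-world model.

    Reconstruction of the social-network growth rule: start from an ER seed
    graph with mean degree 2; each iteration a uniformly chosen node either
    introduces two of its neighbors to each other (if it has >= 2 neighbors)
    or gains one random link; then, with probability ``p_d``, a uniformly
    chosen node is replaced by a newcomer holding a single random link.
    Low ``p_d`` yields small-world graphs with hubs, higher ``p_d`` without.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if not 0.0 <= p_d <= 1.0:
        raise ValueError("p_d must be in [0, 1]")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    rng = _pyrandom.Random(seed)
    nbrs: list[set[int]] = [set() for _ in range(n_nodes)]

    def _add(a: int, b: int) -> None:
        if a != b:
            nbrs[a].add(b)
            nbrs[b].add(a)

    def _other(a: int) -> int:
        v = rng.randrange(n_nodes - 1)
        return v + 1 if v >= a else v

    # ER seed graph with n_nodes edges (mean degree 2)
    n_seed_edges = 0
    while n_seed_edges < n_nodes:
        a = rng.randrange(n_nodes)
        b = rng.randrange(n_nodes)
        if a != b and b not in nbrs[a]:
            _add(a, b)
            n_seed_edges += 1

    for _ in range(iterations):
        u = rng.randrange(n_nodes)
        if len(nbrs[u]) >= 2:
            a, b = rng.sample(sorted(nbrs[u]), 2)
            _add(a, b)
        else:
            _add(u, _other(u))
        if p_d > 0.0 and rng.random() < p_d:
            w = rng.randrange(n_nodes)
            for x in list(nbrs[w]):
                nbrs[w].discard(x)
                nbrs[x].discard(w)
            _add(w, _other(w))

    edges = frozenset(
        (i, j) for i in range(n_nodes) for j in nbrs[i] if i < j
    )
    return NetworkTopology(n_nodes, edges)


def generate_preferential(n_nodes: int, m: int, seed: int = 0) -> NetworkTopology:
    """Linear preferential attachment graph, simplified.

    Uses the Barabási–Albert "bag" process (which can create multi-edges and
    self-loops, like the classical implementation) with ``m`` edges added per
    step, then removes improper connections.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if n_nodes <= m:
        raise ValueError("n_nodes must exceed m")
    state = _pyrandom.getstate()
    try:
        _pyrandom.seed(seed)
        g = ig.Graph.Barabasi(n_nodes, m, implementation="bag", directed=False)
    finally:
        _pyrandom.setstate(state)
    g.simplify()
    edges = frozenset(_canon(s, t) for s, t in g.get_edgelist())
    return NetworkTopology(n_nodes, edges)


def finalize_connected(topology: NetworkTopology) -> NetworkTopology:
    """Restrict to the largest connected component and compact node indices.

    Nodes outside the largest component (isolated nodes in particular) are
    removed; remaining nodes are relabeled 0..k-1 preserving order.
    """
    if topology.n_nodes < 1:
        raise ValueError("empty graph")
    n = topology.n_nodes
    if not topology.edges:
        raise ValueError("graph has no edges; largest component is a single node")
    n_comp, labels = connected_components(topology.adjacency(), directed=False)
    if n_comp == 1:
        return topology
    sizes = np.bincount(labels, minlength=n_comp)
    keep_label = int(np.argmax(sizes))  # ties: lowest component label
    keep = np.flatnonzero(labels == keep_label)
    remap = -np.ones(n, dtype=np.int64)
    remap[keep] = np.arange(len(keep))
    edges = frozenset(
        (int(remap[i]), int(remap[j]))
        for i, j in topology.edges
        if remap[i] >= 0 and remap[j] >= 0
    )
    labels_out = None
    if topology.labels is not None:
        labels_out = tuple(topology.labels[i] for i in keep)
    return NetworkTopology(len(keep), edges, labels_out)


def select_representative(candidates) -> int:
    """Index of the metrics vector closest to the candidate-group mean.

    Each metric is z-scored across candidates (columns with zero spread
    contribute nothing); the candidate minimizing the Euclidean norm of its
    z-score vector wins, ties broken by lowest index.
    """
    X = np.asarray(candidates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need at least one candidate metrics vector")
    if X.shape[0] == 1:
        return 0
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    z = np.zeros_like(X)
    ok = sd > 0
    z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    dist = np.sqrt((z**2).sum(axis=1))
    return int(np.argmin(dist))
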