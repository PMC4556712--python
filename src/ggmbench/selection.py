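"""Fixed-density edge selection from full weight matrices.

The estimators return full matrices; comparisons between them are made at
matched edge counts, so selection simply keeps the k largest absolute
weights.  Tie-break is deterministic: larger signed weight first, then
lexicographic node pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ggmbench.estimators import WeightMatrix

Edge = tuple[int, int]


@dataclass(frozen=True)
class BinaryNetwork:
    """Binarized network of the k strongest estimated connections."""

    n_nodes: int
    edges: frozenset[Edge]
    source_method: str = ""
    k_selected: int = -1

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"invalid edge ({i}, {j})")
        if self.k_selected < 0:
            object.__setattr__(self, "k_selected", len(self.edges))
        elif self.k_selected != len(self.edges):
            raise ValueError("k_selected must equal the number of edges")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


def select_top_k(weights: WeightMatrix | np.ndarray, k: int) -> BinaryNetwork:
    """Keep exactly the k strongest absolute off-diagonal weights."""
    if isinstance(weights, WeightMatrix):
        W, method = weights.values, weights.method
    else:
        W, method = np.asarray(weights, dtype=float), ""
    p = W.shape[0]
    max_k = p * (p - 1) // 2
    if not 0 <= k <= max_k:
        raise ValueError(f"k must be in [0, {max_k}]")
    ii, jj = np.triu_indices(p, 1)
    w = W[ii, jj]
    # np.lexsort: last key is primary -> |w| desc, then w desc, then (i, j) asc
    order = np.lexsort((jj, ii, -w, -np.abs(w)))
    sel = order[:k]
    edges = frozenset(zip(ii[sel].tolist(), jj[sel].tolist()))
    return BinaryNetwork(p, edges, source_method=method, k_selected=k)


def density_variants(true_edge_count: int) -> tuple[int, int, int]:
    """(20% too few, true, 20% too many) edge counts; round half away from zero."""
    if true_edge_count < 0:
        raise ValueError("edge count must be non-negative")
    k_minus = int(math.floor(0.8 * true_edge_count + 0.5))
    k_plus = int(math.floor(1.2 * true_edge_count + 0.5))
    return k_minus, true_edge_count, k_plus


def fixed_density_k(n_nodes: int, density: float = 0.03) -> int:
    """Edge count of the fixed-density rule: floor(density * n(n-1)/2)."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    return int(math.floor(density * n_nodes * (n_nodes - 1) / 2))
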