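"""Recovery evaluation: estimated networks vs. ground truth.

Edge-wise true/false positive rates (overall and by degree-bin pairing),
node-metric discrepancy summaries, and the consistency statistics used for
ROI-matrix analyses (edge overlap, within/between-area connectivity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _edge_sets(estimated, truth):
    if estimated.n_nodes != truth.n_nodes:
        raise ValueError(
            f"node-set mismatch: {estimated.n_nodes} vs {truth.n_nodes}"
        )
    return set(estimated.edges), set(truth.edges)


def tpr_fpr(estimated, truth) -> tuple[float, float]:
    """(TPR, FPR) of an estimated binary network against the true topology.

    TPR = recovered true edges / true edges;
    FPR = spurious edges / non-edges.
    """
    est, tru = _edge_sets(estimated, truth)
    p = truth.n_nodes
    total = p * (p - 1) // 2
    n_true = len(tru)
    n_non = total - n_true
    tpr = len(est & tru) / n_true if n_true else float("nan")
    fpr = len(est - tru) / n_non if n_non else float("nan")
    return tpr, fpr


@dataclass(frozen=True)
class DegreeBinSpec:
    """Per-node degree-bin assignment: bins 1-5 by degree, bin 6 = top nodes."""

    bin_assignment: np.ndarray  # values in 1..6
    top_bin_size: int

    def __post_init__(self) -> None:
        b = np.asarray(self.bin_assignment)
        if b.ndim != 1 or not np.all((b >= 1) & (b <= 6)):
            raise ValueError("bin assignment must be a vector of values in 1..6")
        if int((b == 6).sum()) != self.top_bin_size:
            raise ValueError("bin 6 must contain exactly top_bin_size nodes")


def assign_degree_bins(truth, top_n: int = 50) -> DegreeBinSpec:
    """Split nodes into 5 near-equal degree bins plus a top-degree bin.

    The ``top_n`` highest-degree nodes (degree ties broken by lower node
    index) form bin 6; the rest are sorted by ascending degree and split
    into 5 bins whose sizes differ by at most 1, remainders going to the
    lowest bins.
    """
    deg = truth.degrees() if hasattr(truth, "degrees") else np.asarray(truth)
    n = len(deg)
    if not 0 < top_n < n:
        raise ValueError("top_n must be in (0, n_nodes)")
    order_desc = np.lexsort((np.arange(n), -deg))  # by degree desc, then index
    top = order_desc[:top_n]
    rest = order_desc[top_n:][::-1]  # ascending degree, ties by higher index first
    # re-sort rest ascending with index tie-break for determinism
    rest = rest[np.lexsort((rest, deg[rest]))]
    bins = np.zeros(n, dtype=np.int64)
    bins[top] = 6
    n_rest = n - top_n
    base, extra = divmod(n_rest, 5)
    sizes = [base + (1 if b < extra else 0) for b in range(5)]
    start = 0
    for b, size in enumerate(sizes, start=1):
        bins[rest[start : start + size]] = b
        start += size
    return DegreeBinSpec(bins, top_n)


def binned_tpr_fpr(
    estimated, truth, bins: DegreeBinSpec
) -> tuple[np.ndarray, np.ndarray]:
    """TPR and FPR per unordered degree-bin pairing, as 6x6 matrices.

    Entry (a, b) (0-based; symmetric) covers edges whose endpoints fall in
    bins a+1 and b+1.  Pairings with no true edges (TPR) or no non-edges
    (FPR) are NaN.
    """
    est, tru = _edge_sets(estimated, truth)
    b = np.asarray(bins.bin_assignment) - 1
    if len(b) != truth.n_nodes:
        raise ValueError("bin assignment does not match node count")
    sizes = np.bincount(b, minlength=6).astype(np.int64)

    def _pair_counts(edges) -> np.ndarray:
        M = np.zeros((6, 6), dtype=np.int64)
        if edges:
            ea = np.array(sorted(edges), dtype=np.int64)
            ba, bb = b[ea[:, 0]], b[ea[:, 1]]
            lo, hi = np.minimum(ba, bb), np.maximum(ba, bb)
            np.add.at(M, (lo, hi), 1)
        return M + np.triu(M, 1).T

    n_true = _pair_counts(tru)
    n_hit = _pair_counts(est & tru)
    n_false = _pair_counts(est - tru)
    total_pairs = np.outer(sizes, sizes)
    np.fill_diagonal(total_pairs, sizes * (sizes - 1) // 2)
    n_non = total_pairs - n_true
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(n_true > 0, n_hit / np.maximum(n_true, 1), np.nan)
        fpr = np.where(n_non > 0, n_false / np.maximum(n_non, 1), np.nan)
    return tpr, fpr


def normalized_node_diff(estimated_values, true_values) -> float:
    """Sum of absolute differences after mapping both by the true min/max.

    The linear transform sends min(true) to 0 and max(true) to 1; both
    vectors go through the *same* transform before the absolute differences
    are summed.
    """
    est = np.asarray(estimated_values, dtype=float)
    tru = np.asarray(true_values, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("vectors must have equal length")
    lo, hi = tru.min(), tru.max()
    if hi <= lo:
        raise ValueError("degenerate scale: constant true vector")
    scale = hi - lo
    return float(np.abs((est - lo) / scale - (tru - lo) / scale).sum())


def fpr_transform(fpr: float) -> float:
    """f(FPR) = exp(-100 * FPR); 1 at FPR=0, decreasing in FPR."""
    return float(np.exp(-100.0 * fpr))


def edge_overlap(net_a, net_b) -> float:
    """Proportion of shared edges between two equally dense networks."""
    if net_a.n_nodes != net_b.n_nodes:
        raise ValueError("node-set mismatch")
    ka, kb = len(net_a.edges), len(net_b.edges)
    if ka != kb:
        raise ValueError(f"edge counts differ ({ka} vs {kb}); overlap presumes matched density")
    if ka == 0:
        return 1.0
    return len(set(net_a.edges) & set(net_b.edges)) / ka


def area_connectivity(
    coarse_net, fine_net, mapping
) -> tuple[float, float]:
    """Within- and between-area connectivity of a fine network vs. a coarse one.

    ``mapping[fine_node] = coarse_area``.  Within: fraction of *split* areas
    (>= 2 fine nodes) containing at least one internal fine edge.  Between:
    fraction of coarse-connected area pairs spanned by at least one fine
    edge.  Undefined fractions are NaN.
    """
    mapping = np.asarray(mapping, dtype=np.int64)
    if len(mapping) != fine_net.n_nodes:
        raise ValueError("mapping must cover all fine nodes")
    if mapping.min() < 0 or mapping.max() >= coarse_net.n_nodes:
        raise ValueError("mapping targets unknown coarse areas")
    area_sizes = np.bincount(mapping, minlength=coarse_net.n_nodes)
    split_areas = set(np.flatnonzero(area_sizes >= 2).tolist())
    internally_wired: set[int] = set()
    spanned_pairs: set[tuple[int, int]] = set()
    for i, j in fine_net.edges:
        a, b = int(mapping[i]), int(mapping[j])
        if a == b:
            internally_wired.add(a)
        else:
            spanned_pairs.add((min(a, b), max(a, b)))
    coarse_pairs = set(coarse_net.edges)
    within = (
        len(internally_wired & split_areas) / len(split_areas)
        if split_areas
        else float("nan")
    )
    between = (
        len(spanned_pairs & coarse_pairs) / len(coarse_pairs)
        if coarse_pairs
        else float("nan")
    )
    return within, between
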