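"""Hierarchically nested ROI fixture and consistency analyses.

The fixture emulates a set of nested parcellations: a Gaussian graphical
model is built at the finest level, AR(1) series are simulated there, and
each coarser level's series are the means of its (immediate) finer
children.  Consistency analyses then compare fixed-density networks across
estimation methods, series lengths, and parcellation levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ggmbench.estimators import pearson_correlation, shrinkage_pcor
from ggmbench.ggm import build_ggm
from ggmbench.recovery import area_connectivity, edge_overlap
from ggmbench.selection import fixed_density_k, select_top_k
from ggmbench.timeseries import TimeSeries, simulate_ar1_gaussian
from ggmbench.topology import generate_random, NetworkTopology
from ggmbench.selection import BinaryNetwork


@dataclass(frozen=True)
class RoiFixtureSpec:
    """Nested parcellation sizes (coarse to fine) plus series parameters."""

    sizes: tuple[int, ...] = (68, 114, 219, 448, 1000)
    T: int = 240
    rho: float = 0.5
    density: float = 0.03

    def __post_init__(self) -> None:
        if list(self.sizes) != sorted(self.sizes) or len(set(self.sizes)) != len(
            self.sizes
        ):
            raise ValueError("sizes must be strictly increasing")
        if self.T < 2:
            raise ValueError("T must be >= 2")


@dataclass(frozen=True)
class RoiBundle:
    """Per-level series plus the nesting maps between consecutive levels."""

    spec: RoiFixtureSpec
    series: dict  # level size -> (size, T) ndarray
    child_maps: dict  # finer size -> array mapping finer node -> coarser area
    seed: int

    def mapping_to_level(self, fine_size: int, coarse_size: int) -> np.ndarray:
        """Compose child maps: fine node index -> area index at coarse level."""
        sizes = list(self.spec.sizes)
        i, j = sizes.index(coarse_size), sizes.index(fine_size)
        if i > j:
            raise ValueError("coarse level must not be finer than fine level")
        mapping = np.arange(fine_size)
        for level in range(j, i, -1):
            mapping = self.child_maps[sizes[level]][mapping]
        return mapping


def nested_partition(sizes, seed: int) -> dict:
    """Nesting maps for strictly increasing level sizes.

    Returns ``child_maps[finer_size][finer_node] = coarser_area`` for each
    consecutive level pair, built by randomly splitting blocks so that every
    finer ROI maps to exactly one coarser area.
    """
    sizes = list(sizes)
    rng = np.random.default_rng(seed)
    child_maps: dict[int, np.ndarray] = {}
    for coarse, fine in zip(sizes[:-1], sizes[1:]):
        # start with each coarse area holding one child; add splits
        counts = np.ones(coarse, dtype=np.int64)
        for _ in range(fine - coarse):
            counts[rng.integers(0, coarse)] += 1
        mapping = np.repeat(np.arange(coarse), counts)
        child_maps[fine] = mapping
    return child_maps


def generate_roi_fixture(spec: RoiFixtureSpec, seed: int = 0) -> RoiBundle:
    """Simulate the nested-parcellation bundle.

    The finest level carries a sparse GGM (ER topology at ``spec.density``);
    coarser levels are exact means of their immediate children's series.
    """
    sizes = list(spec.sizes)
    p_fine = sizes[-1]
    child_maps = nested_partition(sizes, seed)
    k = fixed_density_k(p_fine, spec.density)
    topo = generate_random(p_fine, count=k, seed=seed + 1)
    ggm = build_ggm(topo, seed=seed + 2)
    ts = simulate_ar1_gaussian(ggm.cov, spec.T, rho=spec.rho, seed=seed + 3)
    series = {p_fine: ts.values}
    for coarse, fine in zip(sizes[-2::-1], sizes[::-1]):
        mapping = child_maps[fine]
        out = np.zeros((coarse, spec.T))
        counts = np.bincount(mapping, minlength=coarse)
        np.add.at(out, mapping, series[fine])
        series[coarse] = out / counts[:, None]
    return RoiBundle(spec, series, child_maps, seed)


def default_prefix_lengths(T: int = 240, n: int = 16, minimum: int = 15) -> list[int]:
    """Near-geometric grid of prefix lengths from the full series down."""
    grid = np.unique(np.round(np.geomspace(minimum, T, n)).astype(int))
    return sorted(grid.tolist(), reverse=True)


_METHOD_FNS = {
    "pairwise": pearson_correlation,
    "shrinkage": shrinkage_pcor,
}


def _select_level(values: np.ndarray, method: str, rho: float) -> BinaryNetwork:
    p = values.shape[0]
    ts = TimeSeries(values, rho)
    wm = _METHOD_FNS[method](ts)
    return select_top_k(wm, fixed_density_k(p))


def consistency_analysis(
    bundle: RoiBundle,
    methods=("pairwise", "shrinkage"),
    lengths=None,
) -> pd.DataFrame:
    """Fixed-density network consistency across lengths and parcellations.

    For every level and prefix length: estimate with each method, keep the
    3% strongest weights, and report (a) pairwise-vs-partial overlap,
    (b) overlap with the full-length reference network of the same method,
    and (c) within/between-area connectivity against the coarsest level's
    full-length network.  Returns a tidy table.
    """
    for m in methods:
        if m not in _METHOD_FNS:
            raise ValueError(f"unsupported method {m!r} (choose from {list(_METHOD_FNS)})")
    spec = bundle.spec
    if lengths is None:
        lengths = default_prefix_lengths(spec.T)
    rows = []
    coarse_size = spec.sizes[0]
    reference: dict[tuple[int, str], BinaryNetwork] = {}
    for size in spec.sizes:
        for method in methods:
            reference[(size, method)] = _select_level(
                bundle.series[size], method, spec.rho
            )
    for size in spec.sizes:
        for length in lengths:
            if length < 3:
                continue
            if length > spec.T:
                raise ValueError(f"prefix length {length} exceeds T={spec.T}")
            nets = {
                m: _select_level(bundle.series[size][:, :length], m, spec.rho)
                for m in methods
            }
            pair_partial = (
                edge_overlap(nets["pairwise"], nets["shrinkage"])
                if {"pairwise", "shrinkage"} <= set(methods)
                else float("nan")
            )
            for method in methods:
                net = nets[method]
                ref_overlap = edge_overlap(net, reference[(size, method)])
                if size == coarse_size:
                    within = between = float("nan")
                else:
                    mapping = bundle.mapping_to_level(size, coarse_size)
                    within, between = area_connectivity(
                        reference[(coarse_size, method)], net, mapping
                    )
                rows.append(
                    {
                        "level": size,
                        "length": length,
                        "method": method,
                        "k_selected": net.k_selected,
                        "overlap_with_reference": ref_overlap,
                        "overlap_pairwise_partial": pair_partial,
                        "within_area_connectivity": within,
                        "between_area_connectivity": between,
                    }
                )
    return pd.DataFrame(rows)
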