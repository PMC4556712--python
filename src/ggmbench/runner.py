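"""Study orchestration: topology -> GGM -> series -> estimators -> evaluation.

The full factorial design iterates topologies x time-series lengths x
estimators x selection criteria, records recovery rates and network-metric
discrepancies per cell, and writes a reproducible manifest.  Defaults are a
desk-scale profile (p = 200); the study-scale profile (p = 2000) is a matter
of configuration, not code.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ggmbench import io as gio
from ggmbench.estimators import ESTIMATORS, estimate
from ggmbench.ggm import build_ggm
from ggmbench.metrics import metrics_report
from ggmbench.recovery import tpr_fpr
from ggmbench.selection import density_variants, select_top_k
from ggmbench.timeseries import nested_subsets, simulate_ar1_gaussian
from ggmbench.topology import (
    finalize_connected,
    generate_acquaintance,
    generate_preferential,
    generate_random,
)

logger = logging.getLogger("ggmbench")

SELECTION_CRITERIA = ("minus20", "true", "plus20")


@dataclass
class StudyConfig:
    """Configuration of one simulation study run; all randomness is seeded."""

    topologies: list[dict] = field(
        default_factory=lambda: [
            {"kind": "random", "name": "random", "n_nodes": 200, "count": 600},
        ]
    )
    rho: float = 0.5
    lengths: tuple[int, ...] = (125, 250, 750, 2500)
    estimators: tuple[str, ...] = ESTIMATORS
    selection_criteria: tuple[str, ...] = SELECTION_CRITERIA
    replicate_seeds: tuple[int, ...] = (0,)
    variance: float = 2.0
    swi_mode: str = "analytic"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if list(self.lengths) != sorted(self.lengths):
            raise ValueError("lengths must be sorted ascending")
        for est in self.estimators:
            if est not in ESTIMATORS:
                raise ValueError(f"unknown estimator {est!r}")
        for crit in self.selection_criteria:
            if crit not in SELECTION_CRITERIA:
                raise ValueError(f"unknown selection criterion {crit!r}")


def make_topology(spec: dict, seed: int):
    """Build and finalize one topology from a spec dict."""
    kind = spec["kind"]
    n = spec["n_nodes"]
    if kind == "random":
        if "count" in spec:
            topo = generate_random(n, count=spec["count"], seed=seed)
        else:
            topo = generate_random(n, probability=spec["probability"], seed=seed)
    elif kind == "acquaintance":
        topo = generate_acquaintance(n, spec["p_d"], spec["iterations"], seed=seed)
    elif kind == "preferential":
        topo = generate_preferential(n, spec["m"], seed=seed)
    else:
        raise ValueError(f"unknown topology kind {spec['kind']!r}")
    return finalize_connected(topo)


def run_study(config: StudyConfig):
    """Execute the full design; returns (cells DataFrame, artifacts dict).

    Stage failures are recorded in the cell table (column ``error``) and the
    run continues.  With ``config.out_dir`` set, the cell table and a
    manifest with content hashes are written there.
    """
    rows = []
    artifacts: dict = {}
    for spec in config.topologies:
        name = spec.get("name", spec["kind"])
        for rep_seed in config.replicate_seeds:
            t0 = time.perf_counter()
            truth = make_topology(spec, seed=rep_seed)
            ggm = build_ggm(truth, seed=rep_seed + 1, variance=config.variance)
            ts_full = simulate_ar1_gaussian(
                ggm.cov, max(config.lengths), rho=config.rho, seed=rep_seed + 2
            )
            subsets = nested_subsets(ts_full, config.lengths)
            true_metrics = metrics_report(
                truth, weights=ggm.pcor, swi_mode=config.swi_mode
            )
            key = (name, rep_seed)
            artifacts[key] = {
                "topology": truth,
                "ggm": ggm,
                "true_metrics": true_metrics,
                "topology_hash": gio.content_hash(truth),
                "pcor_hash": gio.content_hash(ggm.pcor),
                "series_hash": gio.content_hash(ts_full.values),
            }
            logger.info(
                "prepared %s rep=%d p=%d edges=%d (%.2fs)",
                name, rep_seed, truth.n_nodes, truth.n_edges,
                time.perf_counter() - t0,
            )
            k_minus, k_true, k_plus = density_variants(truth.n_edges)
            k_by_crit = {"minus20": k_minus, "true": k_true, "plus20": k_plus}
            for ts in subsets:
                n_obs = ts.n_timepoints
                for method in config.estimators:
                    row_base = {
                        "topology": name,
                        "replicate_seed": rep_seed,
                        "n_obs": n_obs,
                        "method": method,
                    }
                    try:
                        t1 = time.perf_counter()
                        wm = estimate(method, ts, target_edges=k_true)
                        est_time = time.perf_counter() - t1
                    except Exception as exc:  # record and continue
                        logger.warning("estimation failed: %s (%s)", row_base, exc)
                        rows.append({**row_base, "error": str(exc)})
                        continue
                    for crit in config.selection_criteria:
                        k = k_by_crit[crit]
                        net = select_top_k(wm, k)
                        tpr, fpr = tpr_fpr(net, truth)
                        rep = metrics_report(
                            net, weights=wm, swi_mode=config.swi_mode
                        )
                        rows.append(
                            {
                                **row_base,
                                "criterion": crit,
                                "k_selected": k,
                                "tpr": tpr,
                                "fpr": fpr,
                                "small_worldness": rep.small_worldness,
                                "clustering": rep.global_clustering,
                                "avg_path_length": rep.avg_path_length,
                                "n_components": rep.n_components,
                                "largest_component": rep.largest_component_size,
                                "avg_betweenness": rep.avg_betweenness,
                                "true_small_worldness": true_metrics.small_worldness,
                                "true_n_components": true_metrics.n_components,
                                "estimation_seconds": est_time,
                                "error": "",
                            }
                        )
    cells = pd.DataFrame(rows)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cells.to_csv(out / "cells.tsv", sep="\t", index=False)
        manifest = {
            "config": {
                "topologies": config.topologies,
                "rho": config.rho,
                "lengths": list(config.lengths),
                "estimators": list(config.estimators),
                "selection_criteria": list(config.selection_criteria),
                "replicate_seeds": list(config.replicate_seeds),
                "variance": config.variance,
                "swi_mode": config.swi_mode,
            },
            "artifacts": {
                f"{name}/seed{seed}": {
                    "topology_hash": art["topology_hash"],
                    "pcor_hash": art["pcor_hash"],
                    "series_hash": art["series_hash"],
                    "n_nodes": art["topology"].n_nodes,
                    "n_edges": art["topology"].n_edges,
                }
                for (name, seed), art in artifacts.items()
            },
        }
        gio.write_json(out / "manifest.json", manifest)
    return cells, artifacts
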