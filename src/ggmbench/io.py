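"""Plain-text serialization: edge lists, dense matrices, time series, reports."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from ggmbench.selection import BinaryNetwork
from ggmbench.topology import NetworkTopology


def write_edge_list(path, net, header: dict | None = None) -> None:
    """Edge list as TSV (node_i, node_j per line, i < j, 1-based), with
    ``# key: value`` comment lines for metadata."""
    path = Path(path)
    lines = [f"# n_nodes: {net.n_nodes}"]
    for key, val in (header or {}).items():
        lines.append(f"# {key}: {val}")
    for i, j in sorted(net.edges):
        lines.append(f"{i + 1}\t{j + 1}")
    path.write_text("\n".join(lines) + "\n")


def read_edge_list(path, as_binary: bool = False):
    path = Path(path)
    n_nodes = None
    edges = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("# n_nodes:"):
                n_nodes = int(line.split(":", 1)[1])
            continue
        i, j = (int(x) for x in line.split("\t")[:2])
        edges.append((i - 1, j - 1))
    if n_nodes is None:
        n_nodes = 1 + max((max(e) for e in edges), default=0)
    es = frozenset((min(i, j), max(i, j)) for i, j in edges)
    if as_binary:
        return BinaryNetwork(n_nodes, es)
    return NetworkTopology(n_nodes, es)


def write_matrix_csv(path, M: np.ndarray) -> None:
    np.savetxt(path, np.asarray(M, dtype=float), delimiter=",", fmt="%.12g")


def read_matrix_csv(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def write_timeseries_tsv(path, values: np.ndarray, labels=None) -> None:
    """Rows = nodes, columns = time points, header row with node labels."""
    values = np.asarray(values, dtype=float)
    p = values.shape[0]
    if labels is None:
        labels = [f"node_{i + 1}" for i in range(p)]
    with open(path, "w") as fh:
        fh.write("node\t" + "\t".join(f"t{t + 1}" for t in range(values.shape[1])) + "\n")
        for lab, row in zip(labels, values):
            fh.write(lab + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def read_timeseries_tsv(path) -> tuple[np.ndarray, list[str]]:
    labels, rows = [], []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return np.array(rows), labels


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def content_hash(obj) -> str:
    """Stable sha256 digest of an array, edge set, or string."""
    h = hashlib.sha256()
    if isinstance(obj, np.ndarray):
        h.update(np.ascontiguousarray(obj).tobytes())
        h.update(str(obj.shape).encode())
    elif isinstance(obj, (NetworkTopology, BinaryNetwork)):
        h.update(str(obj.n_nodes).encode())
        h.update(repr(sorted(obj.edges)).encode())
    else:
        h.update(repr(obj).encode())
    return h.hexdigest()
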