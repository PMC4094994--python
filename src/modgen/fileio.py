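"""File formats: edge lists, GML/GraphML, partition TSVs, result bundles.

Conventions: node indices are 0-based everywhere on disk; partition module
labels are 1-based (k in [1, K]).  All writers are deterministic (edges in
canonical sorted order), so identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from .degree_sampling import DegreeDistribution
from .errors import InputError
from .graph_core import GraphSpec, Partition, SimpleGraph

log = logging.getLogger("modgen")

__all__ = [
    "read_graph",
    "write_graph",
    "read_partition",
    "write_partition",
    "write_result",
    "spec_to_dict",
    "spec_from_dict",
    "load_config",
]

_FORMATS = ("edgelist", "gml", "graphml")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("gml", "graphml"):
        return suffix
    return "edgelist"


def _from_nx_any_labels(g: nx.Graph) -> SimpleGraph:
    """Map arbitrary node labels to 0..n-1 (integer-like labels keep their order)."""
    labels = list(g.nodes)
    try:
        labels = sorted(labels, key=int)
        mapping = {lab: int(lab) for lab in labels}
        if set(mapping.values()) != set(range(len(labels))):
            mapping = {lab: i for i, lab in enumerate(labels)}
    except (TypeError, ValueError):
        mapping = {lab: i for i, lab in enumerate(sorted(labels, key=str))}
    edges = []
    dropped = 0
    for u, v in g.edges():
        if u == v:
            dropped += 1
            continue
        edges.append((mapping[u], mapping[v]))
    if dropped:
        log.warning("dropped %d self loop(s) while reading graph", dropped)
    return SimpleGraph.from_edges(len(labels), edges)


def read_graph(path, fmt: str | None = None) -> SimpleGraph:
    """Read a graph from an edge list, GML or GraphML file.

    Edge lists are plain text, one ``i j`` pair of 0-based node indices per
    line; ``#`` lines are comments, and an optional ``# n=<count>`` header
    declares the node count (otherwise max index + 1 is used).  Duplicate
    edges and self loops are dropped with a logged warning count.
    """
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt not in _FORMATS:
        raise InputError(f"unknown graph format {fmt!r}")
    if fmt == "gml":
        return _from_nx_any_labels(nx.read_gml(path, label="id"))
    if fmt == "graphml":
        return _from_nx_any_labels(nx.read_graphml(path))
    edges = set()
    declared_n = None
    self_loops = 0
    duplicates = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if stripped.startswith("n="):
                    declared_n = int(stripped[2:])
                continue
            parts = line.split()
            if len(parts) < 2:
                raise InputError(f"{path}:{lineno}: expected two node indices")
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
            if i == j:
                self_loops += 1
                continue
            edge = (i, j) if i < j else (j, i)
            if edge in edges:
                duplicates += 1
                continue
            edges.add(edge)
    if self_loops or duplicates:
        log.warning(
            "dropped %d self loop(s) and %d duplicate edge(s) from %s",
            self_loops,
            duplicates,
            path,
        )
    n = declared_n if declared_n is not None else (max((j for _, j in edges), default=-1) + 1)
    return SimpleGraph.from_edges(n, edges)


def write_graph(graph: SimpleGraph, path, fmt: str | None = None) -> None:
    """Write a graph; edge lists carry a ``# n=`` header and sorted edges."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "gml":
        nx.write_gml(graph.to_networkx(), path)
        return
    if fmt == "graphml":
        nx.write_graphml(graph.to_networkx(), path)
        return
    if fmt != "edgelist":
        raise InputError(f"unknown graph format {fmt!r}")
    with open(path, "w") as fh:
        fh.write("# undirected simple graph; 0-based node indices\n")
        fh.write(f"# n={graph.n_nodes}\n")
        for i, j in graph.sorted_edges():
            fh.write(f"{i} {j}\n")


def read_partition(path) -> Partition:
    """Read a node->module TSV (node index TAB 1-based module label)."""
    pairs = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise InputError(f"{path}:{lineno}: expected 'node<TAB>module'")
            pairs[int(parts[0])] = int(parts[1])
    if set(pairs) != set(range(len(pairs))):
        raise InputError(f"{path}: node indices must be exactly 0..n-1")
    return Partition(np.array([pairs[i] for i in range(len(pairs))]))


def write_partition(partition: Partition, path) -> None:
    with open(path, "w") as fh:
        fh.write("# node\tmodule (modules are 1-based)\n")
        for node, label in enumerate(partition.assignment):
            fh.write(f"{node}\t{int(label)}\n")


def write_result(result, out_prefix) -> list[Path]:
    """Write a generation result as <prefix>.edgelist, .partition.tsv, .meta.

    The meta file is JSON with the achieved modularity, attempts, seed and a
    spec echo.  Deterministic: identical results give byte-identical files.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    edge_path = prefix.with_suffix(prefix.suffix + ".edgelist")
    part_path = prefix.with_suffix(prefix.suffix + ".partition.tsv")
    meta_path = prefix.with_suffix(prefix.suffix + ".meta")
    write_graph(result.graph, edge_path, fmt="edgelist")
    write_partition(result.partition, part_path)
    meta = {
        "n": result.graph.n_nodes,
        "m": result.graph.n_edges,
        "K": result.partition.n_modules,
        "achieved_Q": result.achieved_q,
        "attempts": result.attempts,
        "seed": result.seed,
        "module_sizes": [int(s) for s in result.partition.sizes],
        "within_edge_fraction": result.within_edge_fraction,
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return [edge_path, part_path, meta_path]


# ---------------------------------------------------------------------------
# spec serialization (config files)
# ---------------------------------------------------------------------------


def _degree_spec_to_obj(value):
    if isinstance(value, DegreeDistribution):
        out = {"family": value.family}
        if value.mean is not None:
            out["mean"] = value.mean
        if value.alpha is not None:
            out["alpha"] = value.alpha
        if value.k_min != 1:
            out["k_min"] = value.k_min
        return out
    if value is None:
        return None
    return [int(x) for x in np.asarray(value).ravel()]


def _degree_spec_from_obj(obj):
    if obj is None:
        return None
    if isinstance(obj, dict):
        return DegreeDistribution(
            obj["family"],
            mean=obj.get("mean"),
            alpha=obj.get("alpha"),
            k_min=int(obj.get("k_min", 1)),
        )
    return np.asarray(obj, dtype=np.int64)


def spec_to_dict(spec: GraphSpec) -> dict:
    size_spec = spec.module_size_spec
    if not isinstance(size_spec, (str, DegreeDistribution)):
        size_spec = [int(s) for s in size_spec]
    elif isinstance(size_spec, DegreeDistribution):
        size_spec = _degree_spec_to_obj(size_spec)
    return {
        "n": spec.n,
        "degree_spec": _degree_spec_to_obj(spec.degree_spec),
        "target_q": spec.target_q,
        "n_modules": spec.n_modules,
        "module_size_spec": size_spec,
        "within_degree_spec": _degree_spec_to_obj(spec.within_degree_spec),
        "epsilon": spec.epsilon,
        "epsilon_dw": spec.epsilon_dw,
        "degree_mean_tol": spec.degree_mean_tol,
        "swaps_per_edge": spec.swaps_per_edge,
        "connect_each_module": spec.connect_each_module,
        "max_attempts": spec.max_attempts,
        "seed": spec.seed,
    }


def spec_from_dict(data: dict) -> GraphSpec:
    data = dict(data)
    size_spec = data.get("module_size_spec", "equal")
    if isinstance(size_spec, dict):
        size_spec = _degree_spec_from_obj(size_spec)
    return GraphSpec(
        n=int(data["n"]),
        degree_spec=_degree_spec_from_obj(data["degree_spec"]),
        target_q=float(data["target_q"]),
        n_modules=int(data.get("n_modules", 1)),
        module_size_spec=size_spec,
        within_degree_spec=_degree_spec_from_obj(data.get("within_degree_spec")),
        epsilon=float(data.get("epsilon", 0.01)),
        epsilon_dw=data.get("epsilon_dw"),
        degree_mean_tol=data.get("degree_mean_tol"),
        swaps_per_edge=int(data.get("swaps_per_edge", 10)),
        connect_each_module=bool(data.get("connect_each_module", False)),
        max_attempts=int(data.get("max_attempts", 1000)),
        seed=data.get("seed"),
    )


def save_spec(spec: GraphSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=True)


def load_config(path) -> dict:
    """Load a YAML config file mirroring the CLI flags."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InputError(f"{path}: config must be a mapping")
    return data
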