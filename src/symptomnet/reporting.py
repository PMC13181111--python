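"""Standard-format exports: CSV tables, JSON results, GraphML networks."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .centrality import strength
from .elasso import edge_list
from .ising import IsingNetwork

__all__ = [
    "network_to_graph",
    "write_network",
    "write_centrality",
    "write_json",
]


def network_to_graph(net: IsingNetwork) -> nx.Graph:
    """Weighted undirected graph with node `threshold` attributes."""
    g = nx.Graph()
    for i, label in enumerate(net.labels):
        g.add_node(label, threshold=float(net.thresholds[i]))
    for a, b, w in edge_list(net):
        g.add_edge(a, b, weight=w)
    return g


def write_network(net: IsingNetwork, out_dir: str | Path, prefix: str) -> dict:
    """Write adjacency, edge-list and thresholds CSVs plus GraphML.

    Returns the mapping of artifact name to path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    adj = pd.DataFrame(net.weights, index=net.labels, columns=net.labels)
    paths["adjacency"] = out_dir / f"{prefix}_adjacency.csv"
    adj.to_csv(paths["adjacency"])

    edges = pd.DataFrame(edge_list(net), columns=["node_a", "node_b", "weight"])
    paths["edges"] = out_dir / f"{prefix}_edges.csv"
    edges.to_csv(paths["edges"], index=False)

    thr = pd.DataFrame({"item": net.labels, "threshold": net.thresholds})
    paths["thresholds"] = out_dir / f"{prefix}_thresholds.csv"
    thr.to_csv(paths["thresholds"], index=False)

    paths["graphml"] = out_dir / f"{prefix}_network.graphml"
    nx.write_graphml(network_to_graph(net), paths["graphml"])
    return paths


def write_centrality(net: IsingNetwork, out_dir: str | Path, prefix: str) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prof = strength(net)
    path = out_dir / f"{prefix}_centrality.csv"
    pd.DataFrame(
        {
            "item": prof.labels,
            "strength": prof.values,
            "strength_z": prof.z_values,
        }
    ).to_csv(path, index=False)
    return path


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))
    return path
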