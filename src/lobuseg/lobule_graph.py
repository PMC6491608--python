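"""Subunit connectivity graph: build, partition, plot and export.

Nodes are segmented subunits positioned at their barycenters and sized by
volume; undirected edges carry the contact ratio (shared interface over mean
total surface) as weight.  Thresholding the edge weights and taking connected
components exposes clusters of well-connected subunits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .quantify import ContactEdge, SubunitRecord
from .types import ConsistencyError, ParameterError

__all__ = [
    "SubunitGraph",
    "ClusterPartition",
    "build_graph",
    "partition_clusters",
    "export_graph",
    "load_graph",
    "plot_graph",
]

SubunitGraph = nx.Graph  # alias: the graph is a plain networkx Graph


@dataclass(frozen=True)
class ClusterPartition:
    """Assignment of every node to exactly one cluster, plus the threshold used."""

    mapping: dict[int, int]
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.mapping.values()))

    def clusters(self) -> list[set[int]]:
        out: dict[int, set[int]] = {}
        for node, cid in self.mapping.items():
            out.setdefault(cid, set()).add(node)
        return [out[cid] for cid in sorted(out)]


def build_graph(
    records: list[SubunitRecord], edges: list[ContactEdge]
) -> SubunitGraph:
    """Assemble the subunit graph from morphometric records and contact edges.

    Node attributes: voxel_count, volume_mm3, bx/by/bz (barycenter, µm).
    Edge attributes: face_count, area_mm2, weight.  Duplicate (i, j)/(j, i)
    edges collapse onto a single undirected edge.
    """
    g = nx.Graph()
    for r in records:
        g.add_node(
            r.label,
            voxel_count=r.voxel_count,
            volume_mm3=r.volume_mm3,
            bx=r.barycenter[0],
            by=r.barycenter[1],
            bz=r.barycenter[2],
        )
    for e in edges:
        for lab in (e.label_i, e.label_j):
            if lab not in g:
                raise ConsistencyError(f"edge endpoint {lab} has no subunit record")
        g.add_edge(
            e.label_i,
            e.label_j,
            face_count=e.face_count,
            area_mm2=e.area_mm2,
            weight=e.weight,
        )
    return g


def partition_clusters(graph: SubunitGraph, weight_threshold: float) -> ClusterPartition:
    """Clusters = connected components after dropping edges below the threshold.

    Isolated nodes become singleton clusters.  Raising the threshold can only
    split clusters, never fuse them.  Cluster ids are assigned in ascending
    order of each component's smallest node label.
    """
    if not (0 <= weight_threshold <= 1):
        raise ParameterError("weight_threshold must be in [0, 1]")
    kept = nx.Graph()
    kept.add_nodes_from(graph.nodes)
    kept.add_edges_from(
        (u, v)
        for u, v, w in graph.edges(data="weight", default=0.0)
        if w >= weight_threshold
    )
    components = sorted(nx.connected_components(kept), key=min)
    mapping = {node: cid for cid, comp in enumerate(components) for node in comp}
    return ClusterPartition(mapping=mapping, threshold=float(weight_threshold))


def greedy_modularity_clusters(graph: SubunitGraph) -> ClusterPartition:
    """Alternative partition: greedy-modularity communities on edge weights."""
    if graph.number_of_nodes() == 0:
        return ClusterPartition(mapping={}, threshold=float("nan"))
    comms = nx.community.greedy_modularity_communities(graph, weight="weight")
    comms = sorted((set(c) for c in comms), key=min)
    mapping = {node: cid for cid, comp in enumerate(comms) for node in comp}
    return ClusterPartition(mapping=mapping, threshold=float("nan"))


def export_graph(graph: SubunitGraph, path, format: str = "graphml") -> None:
    """Write the graph as GraphML or JSON node-link; lossless round-trip."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "json":
        payload = nx.node_link_data(graph, edges="links")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    else:
        raise ParameterError(f"unknown graph format {format!r} (graphml or json)")


def load_graph(path, format: str | None = None) -> SubunitGraph:
    """Read a graph written by :func:`export_graph`."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "graphml"
    if format == "graphml":
        g = nx.read_graphml(path, node_type=int)
        return g
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return nx.node_link_graph(payload, edges="links")
    raise ParameterError(f"unknown graph format {format!r} (graphml or json)")


def plot_graph(graph: SubunitGraph, path, partition: ClusterPartition | None = None):
    """Render the graph in the (x, y) barycenter plane.

    Circle radius scales with subunit volume, line width with contact weight;
    cluster membership (if given) sets the node colour.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = {n: (d.get("bx", 0.0), d.get("by", 0.0)) for n, d in graph.nodes(data=True)}
    vols = [graph.nodes[n].get("volume_mm3", 1.0) for n in graph.nodes]
    vmax = max(vols) if vols else 1.0
    sizes = [3000.0 * v / vmax if vmax > 0 else 300.0 for v in vols]
    weights = [graph.edges[e].get("weight", 0.1) for e in graph.edges]
    widths = [10.0 * w for w in weights]
    colors = (
        [partition.mapping.get(n, 0) for n in graph.nodes]
        if partition is not None
        else "tab:orange"
    )
    fig, ax = plt.subplots(figsize=(7, 6))
    nx.draw_networkx(
        graph,
        pos=pos,
        ax=ax,
        node_size=sizes,
        width=widths,
        node_color=colors,
        cmap="Set2",
        with_labels=True,
        font_size=8,
    )
    ax.set_xlabel("x (µm, apical extremity at x=0)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
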