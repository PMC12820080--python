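"""Backbone sparsification of the item-similarity network and clustering.

A dense cross-scale similarity matrix is hard to read; sparsifying it onto
one *backbone* scale keeps only each outside item's single strongest link
into the backbone.  Clusters of the resulting graph are the semantic
groups the pipeline reports.

Backbone items themselves are linked to their nearest backbone neighbour
(top-1, on by default): without some intra-backbone linkage every
component would contain exactly one backbone item, which cannot produce
the multi-backbone-item groups the method is meant to reveal.  The flag is
configurable because the linkage rule is a modelling choice, not a fact
about the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .embedding import SimilarityMatrix
from .item_bank import ItemBank

__all__ = [
    "Edge",
    "BackboneGraph",
    "ClusterAssignment",
    "sparsify_to_backbone",
    "cluster_graph",
    "export_graph",
    "read_edge_tsv",
    "write_clusters_tsv",
    "read_clusters_tsv",
]

CLUSTER_METHODS = ("components", "greedy_modularity")


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    weight: float
    tie: bool = False  # argmax had multiple equally similar backbone targets


@dataclass(frozen=True)
class BackboneGraph:
    """Directed top-1 links into the backbone scale (undirected for clustering)."""

    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    backbone_scale: str
    include_intra_backbone: bool
    node_scale: Mapping[str, str]
    node_label: Mapping[str, str]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n, scale_id=self.node_scale[n], label=self.node_label[n])
        for e in self.edges:
            g.add_edge(e.source, e.target, weight=e.weight)
        return g


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of graph nodes into semantic groups.

    Labels are contiguous integers from 1, assigned by descending cluster
    size with ties broken by the smallest member id, so the labelling is
    deterministic for a given graph.
    """

    labels: Mapping[str, int]
    n_clusters: int
    method: str

    def members(self, label: int) -> tuple[str, ...]:
        return tuple(sorted(n for n, c in self.labels.items() if c == label))

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.labels.values():
            out[c] = out.get(c, 0) + 1
        return out


def sparsify_to_backbone(
    sim: SimilarityMatrix,
    bank: ItemBank,
    backbone_scale: str,
    include_intra_backbone: bool = True,
) -> BackboneGraph:
    """Keep, per non-backbone item, only its strongest link into the backbone.

    Ties (several backbone items at exactly the maximal similarity) resolve
    to the earliest backbone item in bank order and are flagged on the edge.
    With ``include_intra_backbone``, each backbone item additionally links
    to its most-similar *other* backbone item.
    """
    if sim.ids != bank.item_ids:
        raise ValueError("similarity-matrix ids do not match bank item ids")
    if backbone_scale not in bank.scales:
        raise ValueError(f"backbone scale {backbone_scale!r} not present in bank")
    ids = bank.item_ids
    backbone_idx = [i for i, it in enumerate(bank) if it.scale_id == backbone_scale]
    other_idx = [i for i, it in enumerate(bank) if it.scale_id != backbone_scale]

    edges: list[Edge] = []
    vals = sim.values
    for i in other_idx:
        row = vals[i, backbone_idx]
        j = int(np.argmax(row))  # first max = earliest backbone item in bank order
        tie = bool(np.sum(row == row[j]) > 1)
        edges.append(Edge(ids[i], ids[backbone_idx[j]], float(row[j]), tie))
    if include_intra_backbone:
        for pos, i in enumerate(backbone_idx):
            row = vals[i, backbone_idx].copy()
            row[pos] = -np.inf  # never link to self
            if len(backbone_idx) < 2:
                break
            j = int(np.argmax(row))
            tie = bool(np.sum(row == row[j]) > 1)
            edges.append(Edge(ids[i], ids[backbone_idx[j]], float(row[j]), tie))

    return BackboneGraph(
        nodes=ids,
        edges=tuple(edges),
        backbone_scale=backbone_scale,
        include_intra_backbone=include_intra_backbone,
        node_scale={it.item_id: it.scale_id for it in bank},
        node_label={it.item_id: it.label for it in bank},
    )


def _order_communities(comms: list[set[str]]) -> list[set[str]]:
    return sorted(comms, key=lambda c: (-len(c), min(c)))


def cluster_graph(graph: BackboneGraph, method: str = "components",
                  seed: int = 0) -> ClusterAssignment:
    """Extract semantic clusters from the sparsified graph.

    ``components`` (default) takes connected components of the undirected
    edge set — parameter-free and deterministic.  ``greedy_modularity``
    runs weighted greedy modularity maximization for users who want
    finer communities than pure connectivity gives.  The number of
    clusters is emergent, never forced.
    """
    if method not in CLUSTER_METHODS:
        raise ValueError(f"unknown clustering method {method!r}")
    g = graph.to_networkx()
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if method == "components":
        comms = [set(c) for c in nx.connected_components(g)]
    else:
        comms = [
            set(c)
            for c in nx.community.greedy_modularity_communities(g, weight="weight")
        ]
    labels: dict[str, int] = {}
    for k, comm in enumerate(_order_communities(comms), start=1):
        for node in comm:
            labels[node] = k
    return ClusterAssignment(labels=labels, n_clusters=len(comms), method=method)


def export_graph(graph: BackboneGraph, clusters: ClusterAssignment,
                 path: str | Path, format: str = "edge_tsv") -> None:
    """Write the graph as GraphML (with scale/label/cluster node attributes)
    or as a plain ``source<TAB>target<TAB>weight`` edge list."""
    path = Path(path)
    uncovered = set(graph.nodes) - set(clusters.labels)
    if uncovered:
        raise ValueError(f"clusters do not cover nodes: {sorted(uncovered)}")
    if format == "graphml":
        g = graph.to_networkx()
        for n in g.nodes:
            g.nodes[n]["cluster"] = clusters.labels[n]
        nx.write_graphml(g, path)
    elif format == "edge_tsv":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tweight\n")
            for e in graph.edges:
                fh.write(f"{e.source}\t{e.target}\t{e.weight!r}\n")
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_edge_tsv(path: str | Path) -> tuple[Edge, ...]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()[1:]
    out = []
    for ln in lines:
        s, t, w = ln.split("\t")
        out.append(Edge(s, t, float(w)))
    return tuple(out)


def write_clusters_tsv(clusters: ClusterAssignment, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("item_id\tcluster\n")
        for item_id, label in clusters.labels.items():
            fh.write(f"{item_id}\t{label}\n")


def read_clusters_tsv(path: str | Path) -> ClusterAssignment:
    lines = Path(path).read_text(encoding="utf-8").splitlines()[1:]
    labels = {}
    for ln in lines:
        item_id, label = ln.split("\t")
        labels[item_id] = int(label)
    return ClusterAssignment(labels=labels, n_clusters=len(set(labels.values())),
                             method="components")
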