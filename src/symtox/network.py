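"""Protein similarity network and TRG neighborhood selection.

Nodes are proteins; an edge is a hit passing the published filter
(similarity > 25%, coverage over at least half the query, e-value <= 1e-5).
Clusters are connected components of the thresholded graph — a documented,
conservative stand-in for transitivity clustering, whose parameters were
not published.  Clusters are then joined at the cluster level: two clusters
are adjacent when at least one inter-cluster hit passes the filter, and
only clusters within ``max_steps`` (default 2) of a TRG-containing cluster
are selected.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .align import HitFilter
from .model import AlignmentHit, TrgAnnotation

log = logging.getLogger(__name__)


def build_graph(hits: Iterable[AlignmentHit],
                hit_filter: HitFilter | None = None,
                annotations: dict[str, str] | None = None,
                genome_of: dict[str, str] | None = None) -> nx.Graph:
    """Undirected similarity graph from a hit list.

    Reciprocal hits collapse to one edge keeping the better (smaller)
    e-value.  Node attributes: genome, annotation, trg_class (filled by
    :func:`attach_trg_classes`).
    """
    if hit_filter is None:
        hit_filter = HitFilter()
    annotations = annotations or {}
    genome_of = genome_of or {}
    g = nx.Graph()
    for hit in hits:
        if not hit_filter.passes(hit):
            continue
        u, v = hit.query_id, hit.subject_id
        if u == v:
            continue
        for node in (u, v):
            if node not in g:
                g.add_node(node, genome=genome_of.get(node, ""),
                           annotation=annotations.get(node, ""),
                           trg_class="")
        if g.has_edge(u, v):
            if hit.evalue < g.edges[u, v]["evalue"]:
                g.edges[u, v].update(similarity=hit.percent_similarity,
                                     evalue=hit.evalue)
        else:
            g.add_edge(u, v, similarity=hit.percent_similarity,
                       evalue=hit.evalue)
    return g


def attach_trg_classes(graph: nx.Graph,
                       trg_annotations: Iterable[TrgAnnotation]) -> None:
    for ann in trg_annotations:
        if ann.protein_id in graph:
            graph.nodes[ann.protein_id]["trg_class"] = ann.trg_class


def cluster_graph(graph: nx.Graph) -> dict[str, str]:
    """Connected-component clustering with deterministic labels.

    Components are ordered by their lexicographically smallest member, and
    labelled C0001, C0002, ...  Every node receives a cluster id (isolated
    nodes are singleton clusters).
    """
    components = sorted((sorted(c) for c in nx.connected_components(graph)),
                        key=lambda c: c[0])
    assignment: dict[str, str] = {}
    for i, members in enumerate(components, start=1):
        label = f"C{i:04d}"
        for node in members:
            assignment[node] = label
    return assignment


@dataclass
class TrgNeighborhood:
    """Clusters within max_steps of a TRG-containing cluster."""
    selected: dict[str, int]                    # cluster_id -> step distance
    names: dict[str, str] = field(default_factory=dict)
    max_steps: int = 2

    @property
    def cluster_ids(self) -> list[str]:
        return sorted(self.selected)


def _majority_annotation(graph: nx.Graph, members: Sequence[str]) -> str:
    labels = [graph.nodes[m].get("annotation", "") for m in members]
    labels = [l for l in labels if l]
    if not labels:
        return "unannotated"
    counts = Counter(labels)
    top = max(counts.values())
    return sorted(l for l, c in counts.items() if c == top)[0]


def select_trg_neighborhood(graph: nx.Graph,
                            clusters: dict[str, str],
                            trg_annotations: Iterable[TrgAnnotation],
                            max_steps: int = 2) -> TrgNeighborhood:
    """Select clusters joined to TRG clusters by at most ``max_steps`` steps.

    A cluster-level graph is built (clusters adjacent iff the protein graph
    has an inter-cluster edge, i.e. at least one passing hit between their
    members); selection is a breadth-first expansion from every
    TRG-containing cluster, truncated at ``max_steps``.
    """
    trg_nodes = {a.protein_id for a in trg_annotations}
    members: dict[str, list[str]] = {}
    for node, cid in clusters.items():
        members.setdefault(cid, []).append(node)
    cg = nx.Graph()
    cg.add_nodes_from(members)
    for u, v in graph.edges:
        cu, cv = clusters[u], clusters[v]
        if cu != cv:
            cg.add_edge(cu, cv)
    seeds = sorted(cid for cid, nodes in members.items()
                   if trg_nodes.intersection(nodes))
    if not seeds:
        log.warning("no TRG-containing clusters; neighborhood selection empty")
        return TrgNeighborhood(selected={}, max_steps=max_steps)
    # breadth-first expansion from all TRG clusters at once
    distances: dict[str, int] = {cid: 0 for cid in seeds}
    frontier = list(seeds)
    for step in range(1, max_steps + 1):
        nxt = []
        for cid in frontier:
            for nb in cg.neighbors(cid):
                if nb not in distances:
                    distances[nb] = step
                    nxt.append(nb)
        frontier = nxt
    names = {cid: _majority_annotation(graph, members[cid])
             for cid in distances}
    return TrgNeighborhood(selected=distances, names=names,
                           max_steps=max_steps)


def write_graph(graph: nx.Graph, clusters: dict[str, str],
                path: str) -> None:
    """Serialise the graph as an edge list with a node attribute block."""
    with open(path, "w") as fh:
        fh.write("#nodes\tnode\tgenome\tannotation\ttrg_class\tcluster\n")
        for node in sorted(graph.nodes):
            d = graph.nodes[node]
            fh.write(f"node\t{node}\t{d.get('genome', '')}\t"
                     f"{d.get('annotation', '')}\t{d.get('trg_class', '')}\t"
                     f"{clusters.get(node, '')}\n")
        fh.write("#edges\tu\tv\tsimilarity\tevalue\n")
        for u, v in sorted(map(tuple, map(sorted, graph.edges))):
            d = graph.edges[u, v]
            fh.write(f"edge\t{u}\t{v}\t{d['similarity']:.3f}\t{d['evalue']:.3e}\n")
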