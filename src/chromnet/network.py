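"""Chromatin interaction network construction.

Nodes are open-chromatin peaks (DHS sites); edges are interaction calls whose
two anchors both overlap a peak. Inter-chromosomal calls and edges spanning
more than 1 Mb are removed, duplicate peak-pair calls are merged with PET
counts summed, and connected components are computed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .intervals import GenomicInterval, IntervalIndex, InteractionCall, genomic_distance

logger = logging.getLogger(__name__)

MAX_EDGE_DISTANCE = 1_000_000


@dataclass
class NetworkNode:
    node_id: int
    interval: GenomicInterval
    annotation: str = "unassigned"
    component_id: int = -1


@dataclass
class NetworkEdge:
    u: int
    v: int
    pet_count: int = 1

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValueError("self-edges are not allowed")
        if self.u > self.v:
            self.u, self.v = self.v, self.u


class ChromatinNetwork:
    """A simple undirected PET-weighted graph over annotated peak nodes."""

    def __init__(self, nodes: Iterable[NetworkNode], edges: Iterable[NetworkEdge]):
        self.nodes: dict[int, NetworkNode] = {n.node_id: n for n in nodes}
        self.edges: dict[tuple[int, int], NetworkEdge] = {}
        for e in edges:
            if e.u not in self.nodes or e.v not in self.nodes:
                raise ValueError(f"edge ({e.u}, {e.v}) references unknown node")
            key = (e.u, e.v)
            if key in self.edges:
                self.edges[key].pet_count += e.pet_count
            else:
                self.edges[key] = e
        self.components: list[set[int]] = []
        self._adj: dict[int, set[int]] | None = None
        self._recompute_components()

    # -- structure -----------------------------------------------------

    def _recompute_components(self) -> None:
        g = self.graph()
        comps = sorted(nx.connected_components(g), key=lambda c: min(c))
        self.components = [set(c) for c in comps]
        for cid, comp in enumerate(self.components):
            for nid in comp:
                self.nodes[nid].component_id = cid

    def graph(self) -> nx.Graph:
        """The network as a ``networkx.Graph`` (edge attribute ``pet``)."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.u, e.v, {"pet": e.pet_count}) for e in self.edges.values())
        return g

    def adjacency(self) -> dict[int, set[int]]:
        if self._adj is None:
            adj: dict[int, set[int]] = {nid: set() for nid in self.nodes}
            for u, v in self.edges:
                adj[u].add(v)
                adj[v].add(u)
            self._adj = adj
        return self._adj

    def degree(self, node_id: int) -> int:
        return len(self.adjacency()[node_id])

    def neighbors(self, node_id: int) -> list[int]:
        return sorted(self.adjacency()[node_id])

    def nodes_with_annotation(self, *labels: str) -> list[int]:
        return sorted(n.node_id for n in self.nodes.values() if n.annotation in labels)

    # -- serialization -------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "nodes": [
                {
                    "id": n.node_id,
                    "chrom": n.interval.chrom,
                    "start": n.interval.start,
                    "end": n.interval.end,
                    "annotation": n.annotation,
                    "component": n.component_id,
                }
                for n in sorted(self.nodes.values(), key=lambda n: n.node_id)
            ],
            "edges": [
                {"u": e.u, "v": e.v, "pet": e.pet_count}
                for e in sorted(self.edges.values(), key=lambda e: (e.u, e.v))
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ChromatinNetwork":
        with open(path) as fh:
            doc = json.load(fh)
        nodes = [
            NetworkNode(d["id"], GenomicInterval(d["chrom"], d["start"], d["end"]), d["annotation"])
            for d in doc["nodes"]
        ]
        edges = [NetworkEdge(d["u"], d["v"], d["pet"]) for d in doc["edges"]]
        return cls(nodes, edges)


def build_network(
    calls: Sequence[InteractionCall],
    peaks: Sequence[GenomicInterval],
    extension: int = 250,
    max_distance: int = MAX_EDGE_DISTANCE,
) -> ChromatinNetwork:
    """Build the interaction network from calls and open-chromatin peaks.

    A call survives only if each anchor, extended by ``extension`` bp, overlaps
    at least one peak; each surviving anchor maps to the peak with the largest
    bp overlap (ties to the leftmost peak). Calls whose anchors map to the same
    peak, cross chromosomes, or span more than ``max_distance`` (midpoint to
    midpoint) are dropped. Duplicate peak pairs are merged with PETs summed.

    Peak extension defaults reflect the read-extension already applied upstream
    per assay: 250 bp for ChIA-PET, 0 for HiChIP, 1250 for Hi-C.
    """
    if not peaks:
        raise ValueError("peak list is empty")
    index = IntervalIndex(peaks)

    used: dict[int, NetworkNode] = {}
    merged: dict[tuple[int, int], int] = {}
    n_cross, n_far, n_self, n_offpeak = 0, 0, 0, 0
    for call in calls:
        i = index.best_overlap(call.anchor1, extension)
        j = index.best_overlap(call.anchor2, extension)
        if i is None or j is None:
            n_offpeak += 1
            continue
        if i == j:
            n_self += 1
            continue
        pi, pj = index[i], index[j]
        if pi.chrom != pj.chrom:
            n_cross += 1
            continue
        if genomic_distance(pi, pj) > max_distance:
            n_far += 1
            continue
        if i > j:
            i, j = j, i
        merged[(i, j)] = merged.get((i, j), 0) + call.pet_count
        for k in (i, j):
            if k not in used:
                used[k] = NetworkNode(k, index[k])
    if n_cross or n_far or n_self or n_offpeak:
        logger.info(
            "dropped calls: %d off-peak, %d self-loop, %d inter-chromosomal, %d beyond %d bp",
            n_offpeak, n_self, n_cross, n_far, max_distance,
        )
    edges = [NetworkEdge(u, v, pet) for (u, v), pet in merged.items()]
    return ChromatinNetwork(used.values(), edges)


def connected_components(net: ChromatinNetwork) -> list[set[int]]:
    """The partition of nodes into maximal connected components."""
    return [set(c) for c in net.components]


def network_summary(net: ChromatinNetwork) -> dict:
    """Deterministic count table: nodes, edges, components, per-annotation nodes."""
    ann: dict[str, int] = {}
    for n in net.nodes.values():
        ann[n.annotation] = ann.get(n.annotation, 0) + 1
    return {
        "nodes": len(net.nodes),
        "edges": len(net.edges),
        "components": len(net.components),
        "annotations": dict(sorted(ann.items())),
    }
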