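"""Node annotation.

Each network node receives exactly one regulatory label. Base chromatin states
come from a ChromHMM-style segmentation, disambiguated by a fixed priority
schema; broad-domain and super-enhancer labels are then overlaid on promoter
and enhancer nodes respectively from externally called region sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .intervals import (
    GenomicInterval,
    IntervalIndex,
    StateSegment,
    TssRecord,
    overlap_bp,
    overlaps,
)
from .network import ChromatinNetwork, NetworkEdge, NetworkNode

logger = logging.getLogger(__name__)

#: Disambiguation priority for overlapping chromatin states (1 = strongest).
STATE_PRIORITY = {
    "promoter": 1,
    "enhancer": 1,
    "insulator": 2,
    "poised_promoter": 3,
    "repressed": 4,
    "transcribed": 5,
    "low_signal": 6,
}

ANNOTATION_LABELS = (
    "broad_domain",
    "promoter",
    "super_enhancer",
    "enhancer",
    "insulator",
    "poised_promoter",
    "repressed",
    "transcribed",
    "low_signal",
    "other",
)

TSS_PROMOTER_WINDOW = 2_000


@dataclass
class SuperEnhancerDomain:
    domain_id: int
    interval: GenomicInterval
    member_nodes: list[int] = field(default_factory=list)


def _tss_distance(node: GenomicInterval, tss: TssRecord) -> float:
    """Distance from the nearest node boundary to the TSS (0 if inside the node)."""
    pos = tss.interval.start
    if tss.interval.chrom != node.chrom:
        return float("inf")
    if node.start <= pos < node.end:
        return 0.0
    return float(node.start - pos) if pos < node.start else float(pos - node.end + 1)


def assign_state(
    node: GenomicInterval,
    segments: list[StateSegment],
    tss: list[TssRecord],
) -> str:
    """Base chromatin state of a node under the priority schema.

    Priority: (1) enhancer/promoter, (2) insulator, (3) poised promoter,
    (4) repressed, (5) transcribed, (6) low signal. A node overlapping both
    promoter and enhancer states is a promoter only if within 2 kb of a TSS
    (boundary distance), else an enhancer. Nodes overlapping no segment are
    labeled ``other``.
    """
    hit_states = {
        seg.state for seg in segments if overlaps(node, seg.interval)
    }
    if not hit_states:
        return "other"
    best = min(STATE_PRIORITY[s] for s in hit_states)
    winners = {s for s in hit_states if STATE_PRIORITY[s] == best}
    if winners == {"promoter", "enhancer"}:
        near_tss = any(_tss_distance(node, t) <= TSS_PROMOTER_WINDOW for t in tss)
        return "promoter" if near_tss else "enhancer"
    if len(winners) == 1:
        return winners.pop()
    # ties at lower priorities cannot arise (one state per priority level)
    return sorted(winners, key=lambda s: STATE_PRIORITY[s])[0]


def annotate_states(
    net: ChromatinNetwork,
    segments: list[StateSegment],
    tss: list[TssRecord],
) -> None:
    """Assign every node its base state in place (uses an interval index for speed)."""
    seg_index = IntervalIndex([s.interval for s in segments])
    tss_by_chrom: dict[str, list[TssRecord]] = {}
    for t in tss:
        tss_by_chrom.setdefault(t.interval.chrom, []).append(t)
    n_other = 0
    for node in net.nodes.values():
        hits = seg_index.query(node.interval)
        local_segments = [segments[i] for i in hits]
        local_tss = tss_by_chrom.get(node.interval.chrom, [])
        node.annotation = assign_state(node.interval, local_segments, local_tss)
        if node.annotation == "other":
            n_other += 1
    if n_other:
        logger.info("%d nodes overlap no state segment; labeled 'other'", n_other)


def assign_broad_domains(
    net: ChromatinNetwork, domains: list[GenomicInterval]
) -> int:
    """Overlay broad-domain labels on promoter nodes.

    Per domain, the promoter node(s) with the largest bp overlap are relabeled
    ``broad_domain``; exact ties relabel every tied node. Overlaps with
    non-promoter nodes are ignored. Returns the number of domains that matched
    no promoter node.
    """
    promoters = [n for n in net.nodes.values() if n.annotation in ("promoter", "broad_domain")]
    index = IntervalIndex([n.interval for n in promoters])
    unmatched = 0
    for dom in domains:
        hits = index.query(dom)
        ovs = [(overlap_bp(dom, promoters[i].interval), i) for i in hits]
        ovs = [(o, i) for o, i in ovs if o > 0]
        if not ovs:
            unmatched += 1
            continue
        best = max(o for o, _ in ovs)
        for o, i in ovs:
            if o == best:
                promoters[i].annotation = "broad_domain"
    if unmatched:
        logger.info("%d broad domains overlap no promoter node", unmatched)
    return unmatched


def assign_super_enhancers(
    net: ChromatinNetwork, se_regions: list[GenomicInterval]
) -> list[SuperEnhancerDomain]:
    """Overlay super-enhancer labels on enhancer nodes and record domain membership.

    Every enhancer node overlapping a super-enhancer region is relabeled
    ``super_enhancer``. When regions overlap, a node joins the region with the
    largest bp overlap.
    """
    domains = [SuperEnhancerDomain(i, r) for i, r in enumerate(se_regions)]
    index = IntervalIndex(se_regions)
    for node in net.nodes.values():
        if node.annotation not in ("enhancer", "super_enhancer"):
            continue
        best = index.best_overlap(node.interval)
        if best is None or overlap_bp(node.interval, se_regions[best]) == 0:
            continue
        node.annotation = "super_enhancer"
        domains[best].member_nodes.append(node.node_id)
    for d in domains:
        d.member_nodes.sort()
    return domains


def merge_super_enhancer_nodes(
    net: ChromatinNetwork, domains: list[SuperEnhancerDomain]
) -> ChromatinNetwork:
    """Collapse each super-enhancer domain to a single node.

    Member nodes of a domain become one node whose interval is the union span;
    within-domain edges disappear, edges to outside nodes are re-attached and
    parallel edges merged with PETs summed. Returns a new network; the input is
    unchanged.
    """
    node_to_domain: dict[int, int] = {}
    for d in domains:
        for nid in d.member_nodes:
            if nid in net.nodes:
                node_to_domain[nid] = d.domain_id

    # representative id per domain = smallest member id present in the network
    rep: dict[int, int] = {}
    span: dict[int, tuple[str, int, int]] = {}
    for nid, did in node_to_domain.items():
        iv = net.nodes[nid].interval
        if did not in rep or nid < rep[did]:
            rep[did] = nid
        if did not in span:
            span[did] = (iv.chrom, iv.start, iv.end)
        else:
            chrom, s, e = span[did]
            span[did] = (chrom, min(s, iv.start), max(e, iv.end))

    def mapped(nid: int) -> int:
        return rep[node_to_domain[nid]] if nid in node_to_domain else nid

    new_nodes: dict[int, NetworkNode] = {}
    for n in net.nodes.values():
        m = mapped(n.node_id)
        if m in new_nodes:
            continue
        if n.node_id in node_to_domain:
            chrom, s, e = span[node_to_domain[n.node_id]]
            new_nodes[m] = NetworkNode(m, GenomicInterval(chrom, s, e), "super_enhancer")
        else:
            new_nodes[m] = NetworkNode(m, n.interval, n.annotation)

    merged: dict[tuple[int, int], int] = {}
    for e in net.edges.values():
        u, v = mapped(e.u), mapped(e.v)
        if u == v:
            continue  # within-domain edge
        if u > v:
            u, v = v, u
        merged[(u, v)] = merged.get((u, v), 0) + e.pet_count

    keep = {nid for pair in merged for nid in pair}
    # preserve the node-exists-only-via-edges contract
    new_nodes = {nid: n for nid, n in new_nodes.items() if nid in keep}
    edges = [NetworkEdge(u, v, pet) for (u, v), pet in merged.items()]
    return ChromatinNetwork(new_nodes.values(), edges)
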