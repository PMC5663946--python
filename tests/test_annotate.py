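import pytest

from chromnet.annotate import (
    assign_broad_domains,
    assign_state,
    assign_super_enhancers,
    annotate_states,
    merge_super_enhancer_nodes,
)
from chromnet.intervals import GenomicInterval, StateSegment, TssRecord

from conftest import make_network


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def seg(start, end, state):
    return StateSegment(iv(start, end), state)


def tss(pos, gene="g1", strand="+"):
    return TssRecord(iv(pos, pos + 1), strand, gene)


class TestAssignState:
    node = iv(1000, 1500)

    def test_priority_enhancer_over_insulator(self):
        got = assign_state(self.node, [seg(900, 1200, "enhancer"), seg(1300, 1600, "insulator")], [])
        assert got == "enhancer"

    def test_promoter_enhancer_ambiguity_resolved_by_tss(self):
        segments = [seg(900, 1200, "promoter"), seg(1300, 1600, "enhancer")]
        # TSS 1.5 kb from the node boundary -> promoter
        assert assign_state(self.node, segments, [tss(3000)]) == "promoter"
        # nearest TSS 5 kb away -> enhancer
        assert assign_state(self.node, segments, [tss(6500)]) == "enhancer"
        # no TSS at all -> enhancer
        assert assign_state(self.node, segments, []) == "enhancer"

    def test_promoter_only_needs_no_tss(self):
        assert assign_state(self.node, [seg(900, 1600, "promoter")], []) == "promoter"

    def test_lower_priorities(self):
        got = assign_state(
            self.node, [seg(900, 1600, "repressed"), seg(900, 1600, "transcribed")], []
        )
        assert got == "repressed"
        got = assign_state(
            self.node, [seg(900, 1600, "poised_promoter"), seg(900, 1600, "insulator")], []
        )
        assert got == "insulator"

    def test_no_overlap_is_other(self):
        assert assign_state(self.node, [seg(5000, 6000, "promoter")], []) == "other"


def annotated_network(labels, edges=((0, 1), (1, 2), (2, 3), (3, 4))):
    net = make_network(list(edges), spacing=10_000)
    for nid, lab in labels.items():
        net.nodes[nid].annotation = lab
    return net


class TestBroadDomains:
    def test_largest_overlap_wins(self):
        net = annotated_network({0: "promoter", 1: "promoter", 2: "enhancer"})
        # node intervals are [1000+10000*i, 1500+10000*i)
        # domain overlaps node0 by 300 bp, node1 by 120 bp
        domain = GenomicInterval("chr1", 1200, 11120)
        assign_broad_domains(net, [domain])
        assert net.nodes[0].annotation == "broad_domain"
        assert net.nodes[1].annotation == "promoter"

    def test_exact_tie_crowns_both(self):
        net = annotated_network({0: "promoter", 1: "promoter"})
        domain = GenomicInterval("chr1", 1300, 11200)  # 200 bp on each
        assign_broad_domains(net, [domain])
        assert net.nodes[0].annotation == "broad_domain"
        assert net.nodes[1].annotation == "broad_domain"

    def test_enhancer_overlap_ignored(self):
        net = annotated_network({0: "enhancer", 1: "promoter"})
        unmatched = assign_broad_domains(net, [GenomicInterval("chr1", 900, 1600)])
        assert net.nodes[0].annotation == "enhancer"
        assert unmatched == 1


class TestSuperEnhancers:
    def test_enhancer_nodes_in_region_relabeled(self):
        net = annotated_network({0: "enhancer", 1: "enhancer", 2: "enhancer", 3: "promoter"})
        region = GenomicInterval("chr1", 0, 22_000)  # covers nodes 0-2, and 3? no: node3 at 31000
        domains = assign_super_enhancers(net, [region])
        assert [net.nodes[i].annotation for i in range(3)] == ["super_enhancer"] * 3
        assert net.nodes[3].annotation == "promoter"
        assert domains[0].member_nodes == [0, 1, 2]

    def test_outside_region_unchanged(self):
        net = annotated_network({0: "enhancer"})
        domains = assign_super_enhancers(net, [GenomicInterval("chr1", 500_000, 600_000)])
        assert net.nodes[0].annotation == "enhancer"
        assert domains[0].member_nodes == []


class TestMergeSuperEnhancers:
    def _net_with_domain(self):
        # domain {0,1}; edges inside the domain and to outside node 2
        net = make_network([(0, 1, 2), (0, 2, 3), (1, 2, 5)], spacing=10_000)
        for i in (0, 1):
            net.nodes[i].annotation = "enhancer"
        net.nodes[2].annotation = "promoter"
        domains = assign_super_enhancers(net, [GenomicInterval("chr1", 0, 12_000)])
        return net, domains

    def test_collapse_contract(self):
        net, domains = self._net_with_domain()
        merged = merge_super_enhancer_nodes(net, domains)
        assert len(merged.nodes) == 2
        (edge,) = merged.edges.values()
        assert edge.pet_count == 8  # 3 + 5, the internal edge disappears
        rep = merged.nodes[min(domains[0].member_nodes)]
        assert rep.annotation == "super_enhancer"
        # union span of members
        assert rep.interval.start == 1000 and rep.interval.end == 11_500

    def test_no_internal_edges_preserves_edge_count(self):
        net = make_network([(0, 2), (1, 3)], spacing=10_000)
        for i in (0, 1):
            net.nodes[i].annotation = "enhancer"
        domains = assign_super_enhancers(net, [GenomicInterval("chr1", 0, 12_000)])
        merged = merge_super_enhancer_nodes(net, domains)
        assert len(merged.edges) == len(net.edges)
        assert len(merged.nodes) == len(net.nodes) - 1

    def test_domain_to_domain_edge_survives(self):
        net = make_network([(0, 1), (2, 3), (1, 2)], spacing=10_000)
        for i in range(4):
            net.nodes[i].annotation = "enhancer"
        d = assign_super_enhancers(
            net,
            [GenomicInterval("chr1", 0, 12_000), GenomicInterval("chr1", 20_000, 32_000)],
        )
        merged = merge_super_enhancer_nodes(net, d)
        assert len(merged.nodes) == 2 and len(merged.edges) == 1

    def test_idempotent_and_never_grows(self):
        net, domains = self._net_with_domain()
        merged = merge_super_enhancer_nodes(net, domains)
        assert len(merged.nodes) <= len(net.nodes)
        assert len(merged.edges) <= len(net.edges)
        again = merge_super_enhancer_nodes(merged, domains)
        assert again.nodes.keys() == merged.nodes.keys()
        assert again.edges.keys() == merged.edges.keys()


class TestLabelPartition:
    def test_overlay_preserves_class_totals(self):
        net = make_network([(i, i + 1) for i in range(7)], spacing=10_000)
        segments = []
        for i in range(8):
            state = "promoter" if i < 4 else "enhancer"
            nd = net.nodes[i].interval
            segments.append(StateSegment(nd, state))
        tss_list = [tss(int(net.nodes[i].interval.midpoint)) for i in range(4)]
        annotate_states(net, segments, tss_list)
        n_prom = sum(1 for n in net.nodes.values() if n.annotation == "promoter")
        n_enh = sum(1 for n in net.nodes.values() if n.annotation == "enhancer")
        assign_broad_domains(net, [net.nodes[0].interval])
        assign_super_enhancers(net, [net.nodes[5].interval])
        counts = {}
        for n in net.nodes.values():
            counts[n.annotation] = counts.get(n.annotation, 0) + 1
        assert counts["broad_domain"] + counts["promoter"] == n_prom
        assert counts["super_enhancer"] + counts["enhancer"] == n_enh
        assert sum(counts.values()) == len(net.nodes)
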