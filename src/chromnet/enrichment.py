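"""Observed/expected interaction enrichment between annotation classes.

For every unordered pair of annotation labels (A, B), the expected number of
edges is computed per chromosome as

    Expected(A, B) = sum_C |E_C| * adm_C(A, B) / adm_C(all)

where |E_C| is the observed edge count on chromosome C, adm_C(A, B) is the
number of *admissible* unordered node pairs with one node labeled A and one
labeled B, and adm_C(all) is the number of admissible unordered node pairs
overall. A node pair is admissible when both nodes lie on the same chromosome
and their midpoint distance is at most 1 Mb — the same constraints the network
edges obey — so the expectation corrects for intra-chromosomal testing and the
1 Mb span cap. For A = B the numerator counts unordered within-class pairs.

Enrichment is reported as log2(observed / expected).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotate import SuperEnhancerDomain
from .network import ChromatinNetwork, MAX_EDGE_DISTANCE

logger = logging.getLogger(__name__)


def _label_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class EnrichmentMatrix:
    labels: list[str]
    observed: dict[tuple[str, str], int]
    expected: dict[tuple[str, str], float]

    def log2_ratio(self, a: str, b: str) -> float:
        key = _label_pair(a, b)
        obs = self.observed.get(key, 0)
        exp = self.expected.get(key, 0.0)
        if obs > 0 and exp > 0:
            return math.log2(obs / exp)
        return float("-inf") if exp > 0 else float("nan")

    def to_tsv(self, path: str | Path) -> None:
        """Square TSV of log2 ratios plus a long-format companion of counts."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("annotation\t" + "\t".join(self.labels) + "\n")
            for a in self.labels:
                row = [
                    format(self.log2_ratio(a, b), ".6g") for b in self.labels
                ]
                fh.write(a + "\t" + "\t".join(row) + "\n")
        counts = path.with_name(path.stem + ".counts.tsv")
        with open(counts, "w") as fh:
            fh.write("label_a\tlabel_b\tobserved\texpected\tlog2_ratio\n")
            for a, b in sorted(self.expected):
                fh.write(
                    f"{a}\t{b}\t{self.observed.get((a, b), 0)}\t"
                    f"{self.expected[(a, b)]:.6g}\t{self.log2_ratio(a, b):.6g}\n"
                )


def _admissible_pair_counts(
    net: ChromatinNetwork, max_distance: float
) -> dict[str, tuple[dict[tuple[str, str], int], int]]:
    """Per chromosome: admissible unordered pair counts per label pair, and total."""
    by_chrom: dict[str, list[tuple[float, str]]] = {}
    for n in net.nodes.values():
        by_chrom.setdefault(n.interval.chrom, []).append((n.interval.midpoint, n.annotation))
    out = {}
    for chrom, items in by_chrom.items():
        mids = np.array([m for m, _ in items])
        uniq = sorted({lab for _, lab in items})
        code = {lab: c for c, lab in enumerate(uniq)}
        codes = np.array([code[lab] for _, lab in items])
        n = len(items)
        iu, ju = np.triu_indices(n, k=1)
        ok = np.abs(mids[iu] - mids[ju]) <= max_distance
        ci, cj = codes[iu][ok], codes[ju][ok]
        lo, hi = np.minimum(ci, cj), np.maximum(ci, cj)
        flat = np.bincount(lo * len(uniq) + hi, minlength=len(uniq) ** 2)
        counts: dict[tuple[str, str], int] = {}
        for a in range(len(uniq)):
            for b in range(a, len(uniq)):
                c = int(flat[a * len(uniq) + b])
                if c:
                    counts[(uniq[a], uniq[b])] = c
        out[chrom] = (counts, int(ok.sum()))
    return out


def expected_edges(
    net: ChromatinNetwork,
    label_a: str,
    label_b: str,
    max_distance: float = MAX_EDGE_DISTANCE,
) -> float:
    """Expected number of edges between annotation classes A and B."""
    adm = _admissible_pair_counts(net, max_distance)
    edges_per_chrom: dict[str, int] = {}
    for e in net.edges.values():
        chrom = net.nodes[e.u].interval.chrom
        edges_per_chrom[chrom] = edges_per_chrom.get(chrom, 0) + 1
    key = _label_pair(label_a, label_b)
    total = 0.0
    for chrom, n_edges in edges_per_chrom.items():
        counts, denom = adm[chrom]
        if denom == 0:
            raise ValueError(
                f"chromosome {chrom} has edges but no admissible node pairs"
            )
        total += n_edges * counts.get(key, 0) / denom
    return total


def enrichment_matrix(
    net: ChromatinNetwork, max_distance: float = MAX_EDGE_DISTANCE
) -> EnrichmentMatrix:
    """Observed, expected and log2(observed/expected) for every label pair."""
    adm = _admissible_pair_counts(net, max_distance)
    edges_per_chrom: dict[str, int] = {}
    observed: dict[tuple[str, str], int] = {}
    for e in net.edges.values():
        nu, nv = net.nodes[e.u], net.nodes[e.v]
        chrom = nu.interval.chrom
        edges_per_chrom[chrom] = edges_per_chrom.get(chrom, 0) + 1
        key = _label_pair(nu.annotation, nv.annotation)
        observed[key] = observed.get(key, 0) + 1

    expected: dict[tuple[str, str], float] = {}
    for chrom, n_edges in edges_per_chrom.items():
        counts, denom = adm[chrom]
        if denom == 0:
            raise ValueError(f"chromosome {chrom} has edges but no admissible node pairs")
        for key, cnt in counts.items():
            expected[key] = expected.get(key, 0.0) + n_edges * cnt / denom

    labels = sorted({lab for pair in set(expected) | set(observed) for lab in pair})
    return EnrichmentMatrix(labels, observed, expected)


def se_edge_split(
    net: ChromatinNetwork, domains: list[SuperEnhancerDomain]
) -> tuple[int, int, float]:
    """Split SE-SE edges into within-domain and across-domain counts.

    Returns ``(within, across, within_fraction)``; the fraction is NaN when no
    SE-SE edge exists.
    """
    node_to_domain: dict[int, int] = {}
    for d in domains:
        for nid in d.member_nodes:
            node_to_domain[nid] = d.domain_id
    within = across = 0
    for e in net.edges.values():
        au = net.nodes[e.u].annotation
        av = net.nodes[e.v].annotation
        if au != "super_enhancer" or av != "super_enhancer":
            continue
        du = node_to_domain.get(e.u)
        dv = node_to_domain.get(e.v)
        if du is not None and du == dv:
            within += 1
        else:
            across += 1
    total = within + across
    frac = within / total if total else float("nan")
    return within, across, frac
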