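"""Cell-type specificity of expression (SPM) and enhancer target assignment.

SPM for gene g in cell type c is the cosine similarity between the gene's
cross-tissue expression vector x and the indicator profile of c:
SPM = x_c / ||x||_2, in [0, 1]; the squares over all cell types sum to 1.

Enhancer targets are found by breadth-first search over the interaction
network: from each enhancer or super-enhancer node, the search expands until
the first depth (at most ``max_depth`` edges) at which one or more promoter or
broad-domain nodes are reached; all stop-class nodes at that depth are the
targets and the search does not expand beyond them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalIndex, TssRecord
from .network import ChromatinNetwork

logger = logging.getLogger(__name__)

ENHANCER_CLASSES = ("enhancer", "super_enhancer")
TARGET_CLASSES = ("promoter", "broad_domain")


def read_expression_tsv(path) -> pd.DataFrame:
    """Expression matrix TSV: gene_id column + one column per cell type."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("expression values must be non-negative")
    return df


def spm(expr: pd.DataFrame, cell_type: str) -> pd.Series:
    """SPM score per gene for ``cell_type``; all-zero genes are dropped."""
    if cell_type not in expr.columns:
        raise KeyError(f"unknown cell type {cell_type!r}")
    x = expr.to_numpy(dtype=float)
    norms = np.linalg.norm(x, axis=1)
    keep = norms > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d all-zero genes from SPM", n_dropped)
    col = expr.columns.get_loc(cell_type)
    vals = x[keep, col] / norms[keep]
    return pd.Series(vals, index=expr.index[keep], name=f"spm_{cell_type}")


@dataclass
class TargetAssignment:
    #: enhancer node -> (list of target node ids, depth)
    targets: dict[int, tuple[list[int], int]]

    def target_nodes(self, enhancer_id: int) -> list[int]:
        return self.targets.get(enhancer_id, ([], 0))[0]


def assign_targets(net: ChromatinNetwork, max_depth: int = 4) -> TargetAssignment:
    """BFS promoter/broad-domain targets for every enhancer-class node.

    All stop-class nodes at the minimal depth are kept (several promoters may
    tie at the same depth); promoter nodes are never expanded through.
    """
    adj = net.adjacency()
    targets: dict[int, tuple[list[int], int]] = {}
    for start in net.nodes_with_annotation(*ENHANCER_CLASSES):
        seen = {start}
        frontier = [start]
        depth = 0
        while frontier and depth < max_depth:
            depth += 1
            nxt = []
            found = []
            for v in frontier:
                for u in adj[v]:
                    if u in seen:
                        continue
                    seen.add(u)
                    if net.nodes[u].annotation in TARGET_CLASSES:
                        found.append(u)
                    else:
                        nxt.append(u)
            if found:
                targets[start] = (sorted(found), depth)
                break
            frontier = nxt
    return TargetAssignment(targets)


def nearest_tss_targets(
    net: ChromatinNetwork, tss: list[TssRecord], max_distance: int = 10_000
) -> dict[int, list[str]]:
    """Fallback target mode: genes whose TSS lies within ``max_distance`` bp of
    an enhancer-class node (boundary distance)."""
    out: dict[int, list[str]] = {}
    index = IntervalIndex([t.interval for t in tss])
    for nid in net.nodes_with_annotation(*ENHANCER_CLASSES):
        iv = net.nodes[nid].interval
        hits = index.query(iv, extension=max_distance)
        genes = sorted({tss[i].gene_id for i in hits})
        if genes:
            out[nid] = genes
    return out


def promoter_gene_map(net: ChromatinNetwork, tss: list[TssRecord]) -> dict[int, list[str]]:
    """Genes whose TSS falls inside a promoter/broad-domain node."""
    out: dict[int, list[str]] = {}
    index = IntervalIndex([t.interval for t in tss])
    for nid in net.nodes_with_annotation(*TARGET_CLASSES):
        hits = index.query(net.nodes[nid].interval)
        genes = sorted({tss[i].gene_id for i in hits})
        if genes:
            out[nid] = genes
    return out


def node_spm(
    gene_map: dict[int, list[str]], gene_spm: pd.Series
) -> dict[int, float]:
    """Mean SPM over a node's associated genes; nodes with no scored gene are excluded."""
    out: dict[int, float] = {}
    for nid, genes in gene_map.items():
        vals = [float(gene_spm[g]) for g in genes if g in gene_spm.index]
        if vals:
            out[nid] = sum(vals) / len(vals)
    return out


def enhancer_target_spm(
    assignment: TargetAssignment,
    promoter_genes: dict[int, list[str]],
    gene_spm: pd.Series,
) -> dict[int, float]:
    """Per-enhancer mean SPM over the genes of its target promoter nodes."""
    out: dict[int, float] = {}
    for enh, (tgts, _depth) in assignment.targets.items():
        genes: list[str] = []
        for t in tgts:
            genes.extend(promoter_genes.get(t, []))
        vals = [float(gene_spm[g]) for g in set(genes) if g in gene_spm.index]
        if vals:
            out[enh] = sum(vals) / len(vals)
    return out


def compare_groups(values_a, values_b, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum p-value.

    Exact null distribution for small untied samples, otherwise the normal
    approximation with tie correction. ``alternative='greater'`` tests whether
    group A is stochastically larger.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="auto")
    return float(res.pvalue)
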