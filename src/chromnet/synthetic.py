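"""Synthetic input generator with planted ground truth.

Emulates the statistical structure the analysis assumes, so every pipeline
stage is testable without external data:

* open-chromatin peaks (network nodes) placed on a few chromosomes, each with
  one regulatory label drawn from configurable proportions;
* distance-decaying intra-chromosomal contacts within 1 Mb, with planted
  enrichment multipliers for chosen annotation pairs (broad-domain <->
  super-enhancer, within-domain super-enhancer pairs, promoter-promoter, and a
  mild connectivity boost for broad domains, which are strongly connected hub
  promoters in real networks);
* super-enhancer domains as runs of neighboring nodes, so constituent nodes
  sit close together and within-domain contacts are geometrically possible;
* PET counts, TSS/gene structure, a cell-type expression panel in which
  broad-domain genes and super-enhancer target genes are cell-specific;
* phenotype SNPs planted preferentially in enhancers that target broad
  domains; and
* binned contact matrices with Poisson background and planted focal peaks.

Every draw comes from one seeded generator in a fixed order, so identical
configurations produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .intervals import (
    GenomicInterval,
    InteractionCall,
    SnpRecord,
    StateSegment,
    TssRecord,
    write_bed,
    write_bedpe,
    write_snp_tsv,
    write_state_bed,
    write_tss_bed,
)
from .loops import ContactMatrix

logger = logging.getLogger(__name__)


class GeneratorConfigError(ValueError):
    pass


DEFAULT_PROPORTIONS = {
    "promoter": 0.20,
    "broad_domain": 0.05,
    "enhancer": 0.40,
    "super_enhancer": 0.10,
    "insulator": 0.15,
    "other": 0.10,
}

#: Edge-probability multipliers per unordered label pair; anything absent is 1.
#: The broad-domain entries plant the hub behaviour of broad-domain promoters.
DEFAULT_MULTIPLIERS = {
    frozenset(("broad_domain", "super_enhancer")): 4.0,
    frozenset(("promoter", "promoter")): 2.0,
    frozenset(("broad_domain", "promoter")): 2.0,
    frozenset(("broad_domain", "broad_domain")): 3.0,
}


@dataclass
class LoopBlockConfig:
    """Contact-matrix block: Poisson background with optional planted peaks."""

    n_bins: int = 150
    resolution: int = 5_000
    background_lambda: float = 10.0
    decay_exponent: float = 0.0  # 0 = homogeneous background
    planted: list[tuple[int, int, float]] = field(default_factory=list)  # (i, j, fold)


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 30_000_000
    nodes_per_chrom: int = 600
    proportions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    se_members_per_domain: int = 3
    n_se_domains: int | None = None  # derived from the SE proportion when None
    base_rate: float = 0.19
    alpha: float = 0.3
    decay_scale: int = 50_000  # bp; p = base_rate * (d0 / (d0 + gd))^alpha
    p_cap: float = 0.95
    max_distance: int = 1_000_000
    multipliers: dict = field(default_factory=lambda: dict(DEFAULT_MULTIPLIERS))
    se_same_domain_multiplier: float = 5.0
    pet_mean: float = 4.0
    n_cell_types: int = 23
    specific_level: float = 10.0
    background_level: float = 5.0
    expression_noise: float = 0.1
    snp_rate_per_bp: float = 8e-5
    snp_fold: float = 5.0
    n_control_phenotypes: int = 3
    loop_block: LoopBlockConfig = field(default_factory=LoopBlockConfig)

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise GeneratorConfigError(f"proportions sum to {total}, not 1")
        if any(v < 0 for v in self.proportions.values()):
            raise GeneratorConfigError("proportions must be non-negative")
        if self.alpha <= 0:
            raise GeneratorConfigError("alpha must be positive")
        if any(m < 0 for m in self.multipliers.values()):
            raise GeneratorConfigError("multipliers must be non-negative")
        n_total = self.n_chromosomes * self.nodes_per_chrom
        enhancer_budget = int(
            (self.proportions.get("enhancer", 0) + self.proportions.get("super_enhancer", 0))
            * n_total
        )
        n_dom = self.derived_n_se_domains()
        if n_dom * self.se_members_per_domain > enhancer_budget:
            raise GeneratorConfigError(
                "super-enhancer members exceed the enhancer-class budget"
            )

    def derived_n_se_domains(self) -> int:
        if self.n_se_domains is not None:
            return self.n_se_domains
        n_total = self.n_chromosomes * self.nodes_per_chrom
        n_se = int(round(self.proportions.get("super_enhancer", 0.0) * n_total))
        return n_se // self.se_members_per_domain

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "multipliers" in raw:
            raw["multipliers"] = {
                frozenset(k.split("|")): float(v) for k, v in raw["multipliers"].items()
            }
        if "loop_block" in raw:
            lb = raw["loop_block"]
            lb["planted"] = [tuple(t) for t in lb.get("planted", [])]
            raw["loop_block"] = LoopBlockConfig(**lb)
        return cls(**raw)


@dataclass
class GroundTruth:
    """Generator bookkeeping: everything planted, keyed by node index."""

    labels: list[str]
    intervals: list[GenomicInterval]
    domain_of: dict[int, int]  # SE node -> domain id
    edges: list[tuple[int, int]]
    expected_edge_count: float
    multipliers: dict
    gene_class: dict[str, str] = field(default_factory=dict)  # gene -> specific|background
    snp_nodes: dict[str, list[int]] = field(default_factory=dict)
    planted_loops: list[tuple[int, int, float]] = field(default_factory=list)

    def connected_label_counts(self) -> dict[str, int]:
        touched = {n for e in self.edges for n in e}
        counts: dict[str, int] = {}
        for nid in touched:
            counts[self.labels[nid]] = counts.get(self.labels[nid], 0) + 1
        return dict(sorted(counts.items()))

    def to_json(self, path) -> None:
        doc = {
            "labels": self.labels,
            "intervals": [[iv.chrom, iv.start, iv.end] for iv in self.intervals],
            "domain_of": {str(k): v for k, v in sorted(self.domain_of.items())},
            "edges": [list(e) for e in self.edges],
            "expected_edge_count": self.expected_edge_count,
            "gene_class": self.gene_class,
            "snp_nodes": {k: v for k, v in self.snp_nodes.items()},
            "planted_loops": [list(t) for t in self.planted_loops],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")


@dataclass
class NetworkInputs:
    peaks: list[GenomicInterval]
    calls: list[InteractionCall]
    segments: list[StateSegment]
    bd_regions: list[GenomicInterval]
    se_regions: list[GenomicInterval]
    tss: list[TssRecord]
    truth: GroundTruth

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "peaks": outdir / "peaks.bed",
            "calls": outdir / "calls.bedpe",
            "states": outdir / "states.bed",
            "broad_domains": outdir / "broad_domains.bed",
            "super_enhancers": outdir / "super_enhancers.bed",
            "tss": outdir / "tss.bed",
            "truth": outdir / "truth.json",
        }
        write_bed(paths["peaks"], self.peaks)
        write_bedpe(paths["calls"], self.calls)
        write_state_bed(paths["states"], self.segments)
        write_bed(paths["broad_domains"], self.bd_regions)
        write_bed(paths["super_enhancers"], self.se_regions)
        write_tss_bed(paths["tss"], self.tss)
        self.truth.to_json(paths["truth"])
        return paths


BASE_STATE = {
    "broad_domain": "promoter",
    "super_enhancer": "enhancer",
}


def _place_nodes(cfg: GeneratorConfig, rng: np.random.Generator):
    """Node intervals per chromosome on a 2 kb midpoint grid (no overlaps)."""
    intervals: list[GenomicInterval] = []
    chrom_of: list[int] = []
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        grid = np.arange(5_000, cfg.chrom_length - 5_000, 2_000)
        if cfg.nodes_per_chrom > grid.size:
            raise GeneratorConfigError("too many nodes for the chromosome length")
        mids = np.sort(rng.choice(grid, size=cfg.nodes_per_chrom, replace=False))
        widths = rng.integers(200, 1_001, size=cfg.nodes_per_chrom)
        for m, w in zip(mids.tolist(), widths.tolist()):
            intervals.append(GenomicInterval(chrom, m - int(w) // 2, m - int(w) // 2 + int(w)))
            chrom_of.append(c)
    return intervals, np.array(chrom_of)


def _assign_labels(cfg: GeneratorConfig, rng: np.random.Generator, n_per_chrom: int):
    """Per-chromosome labels: SE domains as runs of consecutive nodes, the rest
    drawn from the renormalized non-SE proportions."""
    n_total = cfg.n_chromosomes * n_per_chrom
    m = cfg.se_members_per_domain
    n_domains = cfg.derived_n_se_domains()

    labels = np.empty(n_total, dtype=object)
    domain_of: dict[int, int] = {}
    dom_id = 0
    per_chrom = [n_domains // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(n_domains % cfg.n_chromosomes):
        per_chrom[i] += 1
    for c in range(cfg.n_chromosomes):
        base = c * n_per_chrom
        starts = rng.permutation(n_per_chrom - m + 1)
        used = np.zeros(n_per_chrom, dtype=bool)
        accepted = 0
        for s in starts.tolist():
            if accepted == per_chrom[c]:
                break
            lo = max(0, s - 1)
            hi = min(n_per_chrom, s + m + 1)  # one-node gap between domains
            if used[lo:hi].any():
                continue
            used[s : s + m] = True
            for k in range(s, s + m):
                labels[base + k] = "super_enhancer"
                domain_of[base + k] = dom_id
            dom_id += 1
            accepted += 1
        if accepted < per_chrom[c]:
            raise GeneratorConfigError("could not place all super-enhancer domains")

    rest_labels = [l for l in cfg.proportions if l != "super_enhancer"]
    rest_p = np.array([cfg.proportions[l] for l in rest_labels])
    rest_p = rest_p / rest_p.sum()
    free = [i for i in range(n_total) if labels[i] is None]
    drawn = rng.choice(rest_labels, size=len(free), p=rest_p)
    for i, lab in zip(free, drawn):
        labels[i] = str(lab)
    return labels.tolist(), domain_of


def _pair_multiplier(cfg, la, lb, same_domain):
    if la == "super_enhancer" and lb == "super_enhancer" and same_domain:
        return cfg.se_same_domain_multiplier
    return cfg.multipliers.get(frozenset((la, lb)), 1.0)


def generate_network_inputs(cfg: GeneratorConfig) -> NetworkInputs:
    """Generate peaks, calls, state/BD/SE/TSS tracks and the ground truth."""
    rng = np.random.default_rng(cfg.seed)
    intervals, chrom_of = _place_nodes(cfg, rng)
    labels, domain_of = _assign_labels(cfg, rng, cfg.nodes_per_chrom)
    n_total = len(intervals)
    mids = np.array([iv.midpoint for iv in intervals])

    edges: list[tuple[int, int]] = []
    expected = 0.0
    for c in range(cfg.n_chromosomes):
        idx = np.flatnonzero(chrom_of == c)
        iu, ju = np.triu_indices(idx.size, k=1)
        gi, gj = idx[iu], idx[ju]
        gd = np.abs(mids[gi] - mids[gj])
        ok = gd <= cfg.max_distance
        gi, gj, gd = gi[ok], gj[ok], gd[ok]
        decay = (cfg.decay_scale / (cfg.decay_scale + gd)) ** cfg.alpha
        mult = np.array(
            [
                _pair_multiplier(
                    cfg,
                    labels[a],
                    labels[b],
                    domain_of.get(a, -1) == domain_of.get(b, -2),
                )
                for a, b in zip(gi.tolist(), gj.tolist())
            ]
        )
        p = np.minimum(cfg.base_rate * decay * mult, cfg.p_cap)
        expected += float(p.sum())
        hit = rng.random(p.size) < p
        edges.extend((int(a), int(b)) for a, b in zip(gi[hit], gj[hit]))

    pets = rng.geometric(1.0 / cfg.pet_mean, size=len(edges))
    calls = [
        InteractionCall(intervals[u], intervals[v], pet_count=int(pet))
        for (u, v), pet in zip(edges, pets.tolist())
    ]

    segments = []
    for i, lab in enumerate(labels):
        if lab == "other":
            continue
        segments.append(StateSegment(intervals[i], BASE_STATE.get(lab, lab)))

    bd_regions = [
        GenomicInterval(iv.chrom, max(0, iv.start - 800), iv.end + 800)
        for i, iv in enumerate(intervals)
        if labels[i] == "broad_domain"
    ]

    se_regions = []
    n_domains = (max(domain_of.values()) + 1) if domain_of else 0
    for d in range(n_domains):
        members = sorted(i for i, dd in domain_of.items() if dd == d)
        chrom = intervals[members[0]].chrom
        lo = min(intervals[i].start for i in members)
        hi = max(intervals[i].end for i in members)
        se_regions.append(GenomicInterval(chrom, max(0, lo - 100), hi + 100, name=f"se_{d}"))

    strands = rng.choice(["+", "-"], size=n_total)
    tss = []
    for i, lab in enumerate(labels):
        if lab in ("promoter", "broad_domain"):
            pos = int(intervals[i].midpoint)
            tss.append(
                TssRecord(
                    GenomicInterval(intervals[i].chrom, pos, pos + 1),
                    str(strands[i]),
                    f"g{i}",
                )
            )

    truth = GroundTruth(
        labels=labels,
        intervals=intervals,
        domain_of=domain_of,
        edges=sorted(edges),
        expected_edge_count=expected,
        multipliers=dict(cfg.multipliers),
    )
    return NetworkInputs(intervals, calls, segments, bd_regions, se_regions, tss, truth)


# ---------------------------------------------------------------------------
# expression


def generate_expression(cfg: GeneratorConfig, truth: GroundTruth, path=None):
    """Expression panel (genes x cell types), query cell type first.

    Genes on broad-domain nodes and genes of promoters directly contacting a
    super-enhancer node are cell-specific (expression concentrated in the
    query type); all other genes are near-uniform across the panel.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    adj: dict[int, set[int]] = {}
    for u, v in truth.edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    gene_nodes = [
        i for i, lab in enumerate(truth.labels) if lab in ("promoter", "broad_domain")
    ]
    specific = set()
    for i in gene_nodes:
        if truth.labels[i] == "broad_domain":
            specific.add(i)
        elif any(truth.labels[u] == "super_enhancer" for u in adj.get(i, ())):
            specific.add(i)

    types = ["query"] + [f"tissue_{t:02d}" for t in range(1, cfg.n_cell_types)]
    rows = []
    for i in gene_nodes:
        gene = f"g{i}"
        if i in specific:
            vec = rng.exponential(0.3, size=cfg.n_cell_types)
            vec[0] = cfg.specific_level * (1 + cfg.expression_noise * rng.standard_normal())
            truth.gene_class[gene] = "specific"
        else:
            vec = cfg.background_level * (
                1 + cfg.expression_noise * rng.standard_normal(cfg.n_cell_types)
            )
            truth.gene_class[gene] = "background"
        rows.append((gene, np.clip(vec, 0, None)))

    df = pd.DataFrame(
        {t: [r[1][k] for r in rows] for k, t in enumerate(types)},
        index=[r[0] for r in rows],
    )
    df.index.name = "gene_id"
    if path is not None:
        df.round(4).to_csv(path, sep="\t")
    return df


# ---------------------------------------------------------------------------
# SNPs


def _truth_targets(truth: GroundTruth, max_depth: int = 4) -> dict[int, list[int]]:
    """Minimal-depth promoter/broad-domain targets per enhancer-class node,
    computed directly on the planted edge list."""
    adj: dict[int, set[int]] = {}
    for u, v in truth.edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    out: dict[int, list[int]] = {}
    stop = ("promoter", "broad_domain")
    for start, lab in enumerate(truth.labels):
        if lab not in ("enhancer", "super_enhancer") or start not in adj:
            continue
        seen = {start}
        frontier = [start]
        depth = 0
        while frontier and depth < max_depth:
            depth += 1
            nxt, found = [], []
            for v in frontier:
                for u in adj.get(v, ()):
                    if u in seen:
                        continue
                    seen.add(u)
                    if truth.labels[u] in stop:
                        found.append(u)
                    else:
                        nxt.append(u)
            if found:
                out[start] = sorted(found)
                break
            frontier = nxt
    return out


def generate_snps(
    cfg: GeneratorConfig,
    truth: GroundTruth,
    e_bd: list[int] | None = None,
    e_p: list[int] | None = None,
    path=None,
) -> list[SnpRecord]:
    """Phenotype SNP table: one disease phenotype with an elevated per-bp SNP
    rate in enhancers targeting broad domains, plus control phenotypes at the
    background rate everywhere.

    The E-BD / E-P partition defaults to the one implied by the planted edges.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    if e_bd is None or e_p is None:
        targets = _truth_targets(truth)
        e_bd, e_p = [], []
        for nid, tgts in targets.items():
            if any(truth.labels[t] == "broad_domain" for t in tgts):
                e_bd.append(nid)
            else:
                e_p.append(nid)
    enh_all = sorted(set(e_bd) | set(e_p))

    snps: list[SnpRecord] = []
    truth.snp_nodes = {}
    phenos = ["disease"] + [f"control_{k + 1}" for k in range(cfg.n_control_phenotypes)]
    for ph in phenos:
        hit_nodes = []
        for nid in enh_all:
            iv = truth.intervals[nid]
            rate = cfg.snp_rate_per_bp * len(iv)
            if ph == "disease" and nid in set(e_bd):
                rate *= cfg.snp_fold
            k = rng.poisson(rate)
            if k > 0:
                hit_nodes.append(nid)
                pos = rng.integers(iv.start, iv.end, size=k)
                for p in sorted(pos.tolist()):
                    snps.append(SnpRecord(ph, GenomicInterval(iv.chrom, p, p + 1)))
        truth.snp_nodes[ph] = hit_nodes
    if path is not None:
        write_snp_tsv(path, snps)
    return snps


# ---------------------------------------------------------------------------
# contact matrices


def generate_contact_matrix(cfg: GeneratorConfig, seed_offset: int = 3):
    """Poisson contact matrix with distance decay and planted focal peaks.

    Returns ``(ContactMatrix, planted)`` where ``planted`` lists the planted
    (i, j, fold) peaks (also recorded for downstream recovery checks).
    """
    lb = cfg.loop_block
    rng = np.random.default_rng(cfg.seed + seed_offset)
    n = lb.n_bins
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    lam = lb.background_lambda / (1.0 + np.abs(i - j)) ** lb.decay_exponent
    lam = np.triu(lam, k=1)
    for pi, pj, fold in lb.planted:
        if pi > pj:
            pi, pj = pj, pi
        lam[pi, pj] *= fold
    counts = rng.poisson(lam)
    m = ContactMatrix("chrS", lb.resolution, counts)
    return m, list(lb.planted)


# ---------------------------------------------------------------------------
# classifier fixtures


def synthetic_feature_table(
    n_per_class: int = 150,
    effect: float = 1.0,
    n_informative: int = 1,
    seed: int = 0,
    n_features: int = 23,
):
    """Standard-normal feature table with class separation planted in the first
    ``n_informative`` features (positive class shifted by ``effect`` SDs).

    Column names follow the real feature table so classifier code paths are
    exercised unchanged.
    """
    from .classify import ALL_FEATURES

    rng = np.random.default_rng(seed)
    names = list(ALL_FEATURES[:n_features])
    X = rng.standard_normal((2 * n_per_class, n_features))
    y = np.array([0] * n_per_class + [1] * n_per_class)
    X[y == 1, :n_informative] += effect
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "label", y)
    df.index.name = "node_id"
    return df
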