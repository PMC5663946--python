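"""Genomic interval primitives and readers/writers for the pipeline's on-disk formats.

All coordinates are 0-based, half-open (BED convention) internally. Inputs that
use 1-based positions (SNP tables) are converted at the reader boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Closed vocabulary of chromatin-state labels consumed from segmentation tracks.
STATE_VOCABULARY = frozenset(
    {
        "promoter",
        "enhancer",
        "insulator",
        "poised_promoter",
        "repressed",
        "transcribed",
        "low_signal",
    }
)


class ParseError(ValueError):
    """Raised for malformed lines in BED/BEDPE/TSV inputs; carries the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class InteractionCall:
    """A pairwise chromatin contact between two anchors, supported by ``pet_count`` read pairs.

    Anchors are stored canonically: ``(anchor1.chrom, anchor1.start) <=
    (anchor2.chrom, anchor2.start)``.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    pet_count: int = 1
    p_value: float | None = None
    q_value: float | None = None

    def __post_init__(self) -> None:
        if self.pet_count < 1:
            raise ValueError(f"pet_count must be >= 1, got {self.pet_count}")
        a, b = self.anchor1, self.anchor2
        if (a.chrom, a.start) > (b.chrom, b.start):
            object.__setattr__(self, "anchor1", b)
            object.__setattr__(self, "anchor2", a)


@dataclass(frozen=True)
class StateSegment:
    """A regulatory-state segment from a ChromHMM-style genome segmentation."""

    interval: GenomicInterval
    state: str

    def __post_init__(self) -> None:
        if self.state not in STATE_VOCABULARY:
            raise ValueError(f"unknown state {self.state!r}")


@dataclass(frozen=True)
class TssRecord:
    """A 1-bp transcription start site with strand and gene identifier."""

    interval: GenomicInterval
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if len(self.interval) != 1:
            raise ValueError("TSS interval must be exactly 1 bp")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/-, got {self.strand!r}")


@dataclass(frozen=True)
class SnpRecord:
    """A 1-bp SNP position associated with a phenotype."""

    phenotype: str
    position: GenomicInterval

    def __post_init__(self) -> None:
        if len(self.position) != 1:
            raise ValueError("SNP position must be exactly 1 bp")


# ---------------------------------------------------------------------------
# interval arithmetic


def overlaps(a: GenomicInterval, b: GenomicInterval, extension: int = 0) -> bool:
    """True iff ``a`` extended by ``extension`` bp on both sides intersects ``b``.

    Extension applies to ``a`` only; at extension 0 the predicate is symmetric.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    if a.chrom != b.chrom:
        return False
    return max(a.start - extension, 0) < b.end and b.start < a.end + extension


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bp of the intersection of two intervals (0 when disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def genomic_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Distance between interval midpoints; infinite across chromosomes."""
    if a.chrom != b.chrom:
        return float("inf")
    return abs(a.midpoint - b.midpoint)


class IntervalIndex:
    """Per-chromosome interval-tree index for fast overlap joins."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        self._items: list[GenomicInterval] = []
        for idx, iv in enumerate(intervals):
            self._items.append(iv)
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)

    def __len__(self) -> int:
        return len(self._items)

    def query(self, iv: GenomicInterval, extension: int = 0) -> list[int]:
        """Indices of stored intervals overlapping ``iv`` extended by ``extension`` bp."""
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        lo = max(iv.start - extension, 0)
        hi = iv.end + extension
        return sorted(hit.data for hit in tree.overlap(lo, hi))

    def best_overlap(self, iv: GenomicInterval, extension: int = 0) -> int | None:
        """Index of the stored interval with the largest bp overlap with ``iv``.

        Overlap is measured on the *extended* query. Ties break to the leftmost
        stored interval (smallest start, then smallest index), so the result is
        deterministic.
        """
        hits = self.query(iv, extension)
        if not hits:
            return None
        ext = GenomicInterval(iv.chrom, max(iv.start - extension, 0), iv.end + extension)
        best = None
        best_key = None
        for i in hits:
            cand = self._items[i]
            key = (-overlap_bp(ext, cand), cand.start, i)
            if best_key is None or key < best_key:
                best, best_key = i, key
        return best

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._items[i]


# ---------------------------------------------------------------------------
# readers


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line


def _parse_coord(token: str, path, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer coordinate {token!r}") from None


def _make_interval(chrom, start, end, path, lineno, **kw) -> GenomicInterval:
    try:
        return GenomicInterval(chrom, start, end, **kw)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from None


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file (>= 3 columns); columns 4 and 6 become name/strand if present."""
    out = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 columns, got {len(cols)}")
        start = _parse_coord(cols[1], path, lineno)
        end = _parse_coord(cols[2], path, lineno)
        name = cols[3] if len(cols) > 3 and cols[3] != "." else None
        strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else None
        out.append(_make_interval(cols[0], start, end, path, lineno, name=name, strand=strand))
    return out


def write_bed(path: str | Path, intervals: Sequence[GenomicInterval], header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t.\t{iv.strand or '.'}\n"
            )


def read_bedpe(path: str | Path) -> list[InteractionCall]:
    """Read a BEDPE file (>= 6 columns); column 7, when present, is the PET count."""
    out = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 6:
            raise ParseError(f"{path}:{lineno}: expected >= 6 columns, got {len(cols)}")
        a = _make_interval(
            cols[0], _parse_coord(cols[1], path, lineno), _parse_coord(cols[2], path, lineno),
            path, lineno,
        )
        b = _make_interval(
            cols[3], _parse_coord(cols[4], path, lineno), _parse_coord(cols[5], path, lineno),
            path, lineno,
        )
        pet = 1
        if len(cols) > 6 and cols[6] not in (".", ""):
            pet = _parse_coord(cols[6], path, lineno)
        out.append(InteractionCall(a, b, pet_count=pet))
    return out


def write_bedpe(path: str | Path, calls: Sequence[InteractionCall], header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tpet\tp\tq\n")
        for c in calls:
            p = "." if c.p_value is None else format(c.p_value, ".6g")
            q = "." if c.q_value is None else format(c.q_value, ".6g")
            fh.write(
                f"{c.anchor1.chrom}\t{c.anchor1.start}\t{c.anchor1.end}\t"
                f"{c.anchor2.chrom}\t{c.anchor2.start}\t{c.anchor2.end}\t"
                f"{c.pet_count}\t{p}\t{q}\n"
            )


def read_state_bed(path: str | Path) -> list[StateSegment]:
    """Read a BED4 segmentation track: column 4 carries the state label."""
    out = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 4:
            raise ParseError(f"{path}:{lineno}: state track needs 4 columns")
        iv = _make_interval(
            cols[0], _parse_coord(cols[1], path, lineno), _parse_coord(cols[2], path, lineno),
            path, lineno,
        )
        if cols[3] not in STATE_VOCABULARY:
            raise ParseError(f"{path}:{lineno}: unknown state {cols[3]!r}")
        out.append(StateSegment(iv, cols[3]))
    return out


def write_state_bed(path: str | Path, segments: Sequence[StateSegment], header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("#chrom\tstart\tend\tstate\n")
        for s in segments:
            fh.write(f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}\t{s.state}\n")


def read_tss_bed(path: str | Path) -> list[TssRecord]:
    """Read TSS definitions: BED with name = gene id and strand in column 6."""
    out = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 6:
            raise ParseError(f"{path}:{lineno}: TSS track needs 6 columns")
        iv = _make_interval(
            cols[0], _parse_coord(cols[1], path, lineno), _parse_coord(cols[2], path, lineno),
            path, lineno,
        )
        try:
            out.append(TssRecord(iv, cols[5], cols[3]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return out


def write_tss_bed(path: str | Path, records: Sequence[TssRecord], header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("#chrom\tstart\tend\tgene_id\tscore\tstrand\n")
        for t in records:
            iv = t.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.gene_id}\t.\t{t.strand}\n")


def read_snp_tsv(path: str | Path) -> list[SnpRecord]:
    """Read a SNP table (phenotype, chrom, pos) with 1-based positions.

    Positions are converted to 0-based half-open at this boundary.
    """
    out = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(f"{path}:{lineno}: SNP table needs 3 columns")
        if lineno == 1 and cols[0].lower() == "phenotype":
            continue
        pos1 = _parse_coord(cols[2], path, lineno)
        if pos1 < 1:
            raise ParseError(f"{path}:{lineno}: 1-based position must be >= 1")
        iv = GenomicInterval(cols[1], pos1 - 1, pos1)
        out.append(SnpRecord(cols[0], iv))
    return out


def write_snp_tsv(path: str | Path, snps: Sequence[SnpRecord], header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("phenotype\tchrom\tpos\n")
        for s in snps:
            fh.write(f"{s.phenotype}\t{s.position.chrom}\t{s.position.start + 1}\n")
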