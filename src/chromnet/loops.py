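"""Significant-interaction calling.

Two callers are provided:

* a hypergeometric caller for protein-centric conformation data (HiChIP-style):
  valid read pairs are assigned to open-chromatin peaks and each peak pair is
  tested against the pairing expected if pair ends combined at random;
* a local-background Poisson caller for binned all-vs-all contact matrices
  (Hi-C-style): each bin pair is compared against four local-background
  footprints (donut, vertical, horizontal, lower-left) and must pass
  Benjamini-Hochberg control under all four.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, IntervalIndex, InteractionCall

logger = logging.getLogger(__name__)

FILTERS = ("donut", "vertical", "horizontal", "lowerleft")


# ---------------------------------------------------------------------------
# hypergeometric caller


@dataclass(frozen=True)
class PeakPairCount:
    """Counts for one peak pair: ``k`` pairs link peaks i and j, which touch
    ``n_i`` and ``n_j`` pairs in total out of ``N`` peak-overlapping pairs."""

    peak_i: int
    peak_j: int
    k: int
    n_i: int
    n_j: int
    N: int

    def __post_init__(self) -> None:
        if self.k > min(self.n_i, self.n_j):
            raise ValueError("k cannot exceed min(n_i, n_j)")
        if max(self.n_i, self.n_j) > self.N:
            raise ValueError("n_i, n_j cannot exceed N")


def hypergeometric_pvalue(c: PeakPairCount) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeom(N, n_i, n_j).

    The model: of the N peak-overlapping pairs, n_i touch peak i; drawing the
    n_j pairs that touch peak j at random, X of them also touch peak i.
    """
    if c.k == 0:
        return 1.0
    return float(stats.hypergeom.sf(c.k - 1, c.N, c.n_i, c.n_j))


def benjamini_hochberg(pvalues: Sequence[float], q: float = 0.05):
    """Benjamini-Hochberg step-up procedure.

    Returns ``(qvalues, reject)`` arrays; q-values are the usual monotone
    adjusted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def call_hichip(
    pairs: Sequence[InteractionCall],
    peaks: Sequence[GenomicInterval],
    extension: int = 250,
    fdr: float = 0.05,
    min_pet: int = 4,
) -> list[InteractionCall]:
    """Call significant peak-peak interactions from valid read pairs.

    Pairs with either end off-peak (after boundary extension) are discarded
    before counting. Per surviving peak pair, an upper-tail hypergeometric
    p-value is computed and corrected by Benjamini-Hochberg; calls must satisfy
    ``q <= fdr`` and be supported by at least ``min_pet`` valid pairs.
    """
    if not peaks:
        raise ValueError("peak list is empty")
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    index = IntervalIndex(peaks)

    pair_k: dict[tuple[int, int], int] = {}
    peak_n: dict[int, int] = {}
    n_total = 0
    for call in pairs:
        i = index.best_overlap(call.anchor1, extension)
        j = index.best_overlap(call.anchor2, extension)
        if i is None or j is None:
            continue
        if i == j:
            continue
        if i > j:
            i, j = j, i
        n_total += 1
        pair_k[(i, j)] = pair_k.get((i, j), 0) + 1
        peak_n[i] = peak_n.get(i, 0) + 1
        peak_n[j] = peak_n.get(j, 0) + 1

    if n_total == 0:
        logger.warning("no valid pairs survive the peak-overlap filter")
        return []

    keys = sorted(pair_k)
    pvals = [
        hypergeometric_pvalue(
            PeakPairCount(i, j, pair_k[(i, j)], peak_n[i], peak_n[j], n_total)
        )
        for i, j in keys
    ]
    qvals, reject = benjamini_hochberg(pvals, q=fdr)

    out = []
    for (i, j), p, qv, rej in zip(keys, pvals, qvals, reject):
        k = pair_k[(i, j)]
        if rej and k >= min_pet:
            out.append(
                InteractionCall(index[i], index[j], pet_count=k, p_value=float(p), q_value=float(qv))
            )
    return out


# ---------------------------------------------------------------------------
# contact matrices and the four-filter Poisson caller


@dataclass
class ContactMatrix:
    """A binned intra-chromosomal contact matrix stored as a dense upper-triangular
    array; ``count(i, j)`` is symmetric by contract."""

    chrom: str
    resolution: int
    counts: np.ndarray  # square, upper-triangular storage

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        # store upper-triangular; symmetric input is mirrored, not summed
        if np.array_equal(c, c.T):
            self.counts = np.triu(c)
        else:
            self.counts = np.triu(c) + np.tril(c, -1).T

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def count(self, i: int, j: int):
        if i > j:
            i, j = j, i
        return self.counts[i, j]

    def bin_interval(self, b: int) -> GenomicInterval:
        return GenomicInterval(self.chrom, b * self.resolution, (b + 1) * self.resolution)


def read_contact_matrix(path: str | Path, max_bins: int = 20000) -> ContactMatrix:
    """Read a sparse 3-column text matrix (bin_i, bin_j, count) with a header
    carrying ``#chrom=<name>`` and ``#resolution=<bp>`` sidecar lines."""
    chrom = None
    resolution = None
    triples = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("chrom="):
                    chrom = body.split("=", 1)[1]
                elif body.startswith("resolution="):
                    resolution = int(body.split("=", 1)[1])
                continue
            cols = line.split("\t")
            triples.append((int(cols[0]), int(cols[1]), int(cols[2])))
    if chrom is None or resolution is None:
        raise ValueError(f"{path}: missing #chrom= / #resolution= header")
    n = 1 + max((max(i, j) for i, j, _ in triples), default=0)
    if n > max_bins:
        raise ValueError(f"{path}: matrix of {n} bins exceeds limit {max_bins}")
    m = np.zeros((n, n), dtype=np.int64)
    for i, j, c in triples:
        if i > j:
            i, j = j, i
        m[i, j] += c
    return ContactMatrix(chrom, resolution, m)


def write_contact_matrix(path: str | Path, m: ContactMatrix) -> None:
    with open(path, "w") as fh:
        fh.write(f"#chrom={m.chrom}\n#resolution={m.resolution}\n")
        ii, jj = np.nonzero(m.counts)
        for i, j in zip(ii.tolist(), jj.tolist()):
            fh.write(f"{i}\t{j}\t{int(m.counts[i, j])}\n")


@dataclass
class LocalFilterResult:
    i: int
    j: int
    observed: int
    expected: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    q_values: dict[str, float] = field(default_factory=dict)


class _UpperTriField:
    """Prefix-sum machinery over the valid upper-triangular region of a matrix,
    giving O(1) footprint sums clipped to bounds and to the triangle."""

    def __init__(self, counts: np.ndarray):
        n = counts.shape[0]
        valid = np.triu(np.ones((n, n), dtype=np.int64), k=1)
        vals = np.triu(counts, k=1)
        self.n = n
        self._sat_vals = np.zeros((n + 1, n + 1))
        self._sat_cnt = np.zeros((n + 1, n + 1))
        self._sat_vals[1:, 1:] = vals.cumsum(0).cumsum(1)
        self._sat_cnt[1:, 1:] = valid.cumsum(0).cumsum(1)

    def box(self, r0: int, r1: int, c0: int, c1: int) -> tuple[float, float]:
        """(sum, cell count) over rows [r0, r1] x cols [c0, c1], clipped."""
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, self.n - 1), min(c1, self.n - 1)
        if r0 > r1 or c0 > c1:
            return 0.0, 0.0
        sv, sc = self._sat_vals, self._sat_cnt
        s = sv[r1 + 1, c1 + 1] - sv[r0, c1 + 1] - sv[r1 + 1, c0] + sv[r0, c0]
        c = sc[r1 + 1, c1 + 1] - sc[r0, c1 + 1] - sc[r1 + 1, c0] + sc[r0, c0]
        return float(s), float(c)


def _footprints(field: _UpperTriField, i: int, j: int, P: int, W: int):
    """Background (sum, count) per filter around (i, j), peak box excluded.

    Footprint geometry follows the local-filter scheme for focal contact peaks:
    donut = square annulus with half-widths P..W; vertical / horizontal =
    3-wide column / row bands of half-height W; lower-left = the quadrant
    between P and W below-left of (i, j). Each excludes the (2P+1)^2 peak box
    centred on (i, j) and is clipped to bounds and the upper triangle.
    """

    peak = field.box(i - P, i + P, j - P, j + P)

    out = {}
    big = field.box(i - W, i + W, j - W, j + W)
    out["donut"] = (big[0] - peak[0], big[1] - peak[1])

    vert = field.box(i - W, i + W, j - 1, j + 1)
    vpeak = field.box(i - P, i + P, j - 1, j + 1)
    out["vertical"] = (vert[0] - vpeak[0], vert[1] - vpeak[1])

    horiz = field.box(i - 1, i + 1, j - W, j + W)
    hpeak = field.box(i - 1, i + 1, j - P, j + P)
    out["horizontal"] = (horiz[0] - hpeak[0], horiz[1] - hpeak[1])

    # quadrant strictly below-left of the peak box, within W
    ll = field.box(i + 1, i + W, j - W, j - 1)
    llpeak = field.box(i + 1, i + P, j - P, j - 1)
    out["lowerleft"] = (ll[0] - llpeak[0], ll[1] - llpeak[1])
    return out


def local_filter_expected(
    m: ContactMatrix, i: int, j: int, P: int = 20, W: int = 40
) -> dict[str, float]:
    """Mean background count under each of the four footprints around bin pair (i, j).

    Raises ``ValueError`` when every footprint is empty (fully out of bounds).
    """
    if not 0 <= i < j:
        raise ValueError("require 0 <= i < j")
    if P >= W:
        raise ValueError("require P < W")
    field = _UpperTriField(m.counts)
    fps = _footprints(field, i, j, P, W)
    expected = {}
    for name, (s, c) in fps.items():
        if c == 0:
            raise ValueError(f"footprint {name} empty at ({i}, {j})")
        expected[name] = s / c
    return expected


def _poisson_sf(observed: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Upper-tail P(Pois(lam) >= observed); lam = 0 gives 0 when observed > 0, else 1."""
    p = np.ones_like(lam, dtype=float)
    pos = lam > 0
    p[pos] = stats.poisson.sf(observed[pos] - 1, lam[pos])
    zero_lam = ~pos
    p[zero_lam & (observed > 0)] = 0.0
    return p


def call_hic(
    m: ContactMatrix,
    P: int = 20,
    W: int = 40,
    fdr: float = 0.025,
    max_distance: int = 1_000_000,
) -> list[InteractionCall]:
    """Call focal contact peaks from a binned matrix with four local filters.

    Candidate bin pairs satisfy ``2 * resolution < distance <= max_distance``
    (the near-diagonal violates the local background model). For each candidate,
    an upper-tail Poisson p-value is computed against each filter's expected
    background; Benjamini-Hochberg control is applied separately per filter and
    a call is emitted only if it passes all four at ``q <= fdr``.
    """
    counts = m.counts
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("contact counts must be integers")
        counts = counts.astype(np.int64)
    n = m.n_bins
    max_lag = max_distance // m.resolution
    field = _UpperTriField(counts)

    cand = []
    for i in range(n):
        for j in range(i + 3, min(n, i + max_lag + 1)):
            cand.append((i, j))
    if not cand:
        return []

    obs = np.array([counts[i, j] for i, j in cand], dtype=np.int64)
    lam = {f: np.empty(len(cand)) for f in FILTERS}
    keep = np.ones(len(cand), dtype=bool)
    for idx, (i, j) in enumerate(cand):
        fps = _footprints(field, i, j, P, W)
        for f in FILTERS:
            s, c = fps[f]
            if c == 0:
                keep[idx] = False
                break
            lam[f][idx] = s / c
    if not np.all(keep):
        logger.info("skipped %d bin pairs with empty footprints", int((~keep).sum()))

    idx_keep = np.flatnonzero(keep)
    reject_all = np.ones(idx_keep.size, dtype=bool)
    pq = {}
    for f in FILTERS:
        p = _poisson_sf(obs[idx_keep], lam[f][idx_keep])
        qv, rej = benjamini_hochberg(p, q=fdr)
        reject_all &= rej
        pq[f] = (p, qv)

    out = []
    for local_pos in np.flatnonzero(reject_all):
        gi = idx_keep[local_pos]
        i, j = cand[gi]
        worst = max(pq[f][1][local_pos] for f in FILTERS)
        worst_p = max(pq[f][0][local_pos] for f in FILTERS)
        out.append(
            InteractionCall(
                m.bin_interval(i),
                m.bin_interval(j),
                pet_count=int(obs[gi]),
                p_value=float(worst_p),
                q_value=float(worst),
            )
        )
    return out
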