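"""Genomic interval arithmetic and noncoding target-region geometry.

The burden analysis counts somatic mutations in each gene's noncoding
*target region*: the transcribed span extended by a symmetric flank
(default +-100 kbp), minus every protein-coding (CDS) base of *any* gene.
Everything here operates on 0-based half-open coordinates; conversion from
1-based input dialects happens at the I/O boundary.

The CDS exclusion deliberately uses the union of CDS over all genes, not
only the focal gene: a flank that crosses a neighbouring gene must not
pick up that gene's coding bases. Strand is stored but ignored for
geometry -- flanks are symmetric upstream and downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

#: Default symmetric flank around the transcribed span, in bp.
DEFAULT_FLANK_BP = 100_000

# Functional classes assigned by :func:`classify_variant`.
CODING = "coding"
NONCODING_TARGET = "noncoding_target"
NONCODING_OTHER = "noncoding_other"

_EMPTY = np.empty(0, dtype=np.int64)


class RegionError(ValueError):
    """Raised for invalid intervals or mismatched chromosomes."""


@dataclass(frozen=True)
class IntervalSet:
    """Sorted, disjoint half-open intervals on a single chromosome.

    Instances are immutable; construct through :meth:`from_pairs` (which
    sorts and merges) or the set-algebra methods, all of which preserve
    the sorted/disjoint invariant.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray

    # -- construction -------------------------------------------------

    @classmethod
    def empty(cls, chrom: str) -> "IntervalSet":
        return cls(chrom, _EMPTY, _EMPTY)

    @classmethod
    def from_pairs(cls, chrom: str, pairs: Iterable[tuple[int, int]]) -> "IntervalSet":
        """Build a minimal sorted disjoint set; overlapping and abutting
        input intervals are merged."""
        pairs = [(int(s), int(e)) for s, e in pairs]
        for s, e in pairs:
            if s >= e:
                raise RegionError(f"invalid interval [{s}, {e}) on {chrom}: start >= end")
        if not pairs:
            return cls.empty(chrom)
        arr = np.asarray(sorted(pairs), dtype=np.int64)
        starts, ends = arr[:, 0], arr[:, 1]
        cummax = np.maximum.accumulate(ends)
        brk = np.empty(len(starts), dtype=bool)
        brk[0] = True
        brk[1:] = starts[1:] > cummax[:-1]  # '>' so abutting intervals merge
        idx = np.flatnonzero(brk)
        m_ends = cummax[np.append(idx[1:] - 1, len(starts) - 1)]
        return cls(chrom, starts[idx].copy(), m_ends.copy())

    # -- basic queries -------------------------------------------------

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def is_empty(self) -> bool:
        return len(self.starts) == 0

    @property
    def total_length_bp(self) -> int:
        return int(np.sum(self.ends - self.starts))

    def pairs(self) -> list[tuple[int, int]]:
        return [(int(s), int(e)) for s, e in zip(self.starts, self.ends)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    __hash__ = None  # type: ignore[assignment]

    def contains(self, positions) -> np.ndarray:
        """Vectorised point membership: True where a position falls in
        one of the intervals."""
        pos = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        if self.is_empty:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(self.starts, pos, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] < self.ends[idx[ok]]
        return ok

    def contains_point(self, pos: int) -> bool:
        return bool(self.contains(pos)[0])

    def overlaps_span(self, start: int, end: int) -> bool:
        """True if any interval intersects [start, end)."""
        if self.is_empty or start >= end:
            return False
        i = np.searchsorted(self.ends, start, side="right")
        return i < len(self.starts) and self.starts[i] < end

    # -- algebra -------------------------------------------------------

    def _check_chrom(self, other: "IntervalSet") -> None:
        if self.chrom != other.chrom:
            raise RegionError(
                f"chromosome mismatch: {self.chrom!r} vs {other.chrom!r}"
            )

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        self._check_chrom(other)
        if self.is_empty or other.is_empty:
            return self
        out_s: list[int] = []
        out_e: list[int] = []
        bs, be = other.starts, other.ends
        for a0, a1 in zip(self.starts, self.ends):
            lo = np.searchsorted(be, a0, side="right")
            hi = np.searchsorted(bs, a1, side="left")
            cur = int(a0)
            for j in range(lo, hi):
                if bs[j] > cur:
                    out_s.append(cur)
                    out_e.append(int(bs[j]))
                cur = max(cur, int(be[j]))
            if cur < a1:
                out_s.append(cur)
                out_e.append(int(a1))
        return IntervalSet(
            self.chrom,
            np.asarray(out_s, dtype=np.int64),
            np.asarray(out_e, dtype=np.int64),
        )

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        self._check_chrom(other)
        if self.is_empty or other.is_empty:
            return IntervalSet.empty(self.chrom)
        out_s: list[int] = []
        out_e: list[int] = []
        bs, be = other.starts, other.ends
        for a0, a1 in zip(self.starts, self.ends):
            lo = np.searchsorted(be, a0, side="right")
            hi = np.searchsorted(bs, a1, side="left")
            for j in range(lo, hi):
                s = max(int(a0), int(bs[j]))
                e = min(int(a1), int(be[j]))
                if s < e:
                    out_s.append(s)
                    out_e.append(e)
        return IntervalSet(
            self.chrom,
            np.asarray(out_s, dtype=np.int64),
            np.asarray(out_e, dtype=np.int64),
        )

    def union(self, other: "IntervalSet") -> "IntervalSet":
        self._check_chrom(other)
        return IntervalSet.from_pairs(self.chrom, self.pairs() + other.pairs())

    def clip(self, start: int, end: int) -> "IntervalSet":
        if start >= end:
            return IntervalSet.empty(self.chrom)
        return self.intersect(IntervalSet.from_pairs(self.chrom, [(start, end)]))


def merge_intervals(chrom: str, raw: Iterable[tuple[int, int]]) -> IntervalSet:
    """Minimal sorted disjoint representation of raw (possibly
    overlapping or abutting) intervals."""
    return IntervalSet.from_pairs(chrom, raw)


def subtract_intervals(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Per-base set difference a \\ b."""
    return a.subtract(b)


# ---------------------------------------------------------------------
# Gene models and target regions
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene's transcribed span plus its exon and CDS structure.

    Invariant: cds is a subset of exons, which lie within
    [tx_start, tx_end). Violations raise at construction.
    """

    gene_id: str
    chrom: str
    tx_start: int
    tx_end: int
    exons: IntervalSet
    cds: IntervalSet
    symbol: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise RegionError(f"gene {self.gene_id}: empty transcribed span")
        if self.strand not in ("+", "-"):
            raise RegionError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        for iset, name in ((self.exons, "exons"), (self.cds, "cds")):
            if iset.chrom != self.chrom:
                raise RegionError(f"gene {self.gene_id}: {name} on wrong chromosome")
        span = IntervalSet.from_pairs(self.chrom, [(self.tx_start, self.tx_end)])
        if not self.exons.subtract(span).is_empty:
            raise RegionError(f"gene {self.gene_id}: exons outside transcribed span")
        if not self.cds.subtract(self.exons).is_empty:
            raise RegionError(f"gene {self.gene_id}: CDS outside exons")

    @property
    def span_bp(self) -> int:
        return self.tx_end - self.tx_start


@dataclass(frozen=True)
class TargetRegion:
    """A gene's noncoding target region and its length (the denominator
    of the burden rate). length_bp == 0 flags a degenerate gene whose
    window is entirely coding; callers keep the row but mark the rate
    undefined."""

    gene_id: str
    regions: IntervalSet
    length_bp: int


def union_cds(genes: Sequence[GeneModel]) -> dict[str, IntervalSet]:
    """Union of CDS intervals of all genes, per chromosome."""
    pairs: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        pairs.setdefault(g.chrom, []).extend(g.cds.pairs())
    return {c: IntervalSet.from_pairs(c, p) for c, p in pairs.items()}


def build_target_region(
    gene: GeneModel,
    all_cds: Mapping[str, IntervalSet],
    flank_bp: int = DEFAULT_FLANK_BP,
    chrom_lengths: Mapping[str, int] | None = None,
) -> TargetRegion:
    """Window [tx_start - flank, tx_end + flank), clipped to the
    chromosome, minus the CDS union of all genes."""
    if flank_bp < 0:
        raise RegionError("flank_bp must be >= 0")
    lo = max(0, gene.tx_start - flank_bp)
    hi = gene.tx_end + flank_bp
    if chrom_lengths is not None:
        hi = min(hi, int(chrom_lengths[gene.chrom]))
    window = IntervalSet.from_pairs(gene.chrom, [(lo, hi)])
    cds = all_cds.get(gene.chrom, IntervalSet.empty(gene.chrom))
    regions = window.subtract(cds)
    return TargetRegion(gene.gene_id, regions, regions.total_length_bp)


def build_all_targets(
    genes: Sequence[GeneModel],
    flank_bp: int = DEFAULT_FLANK_BP,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, TargetRegion]:
    all_cds = union_cds(genes)
    return {
        g.gene_id: build_target_region(g, all_cds, flank_bp, chrom_lengths)
        for g in genes
    }


def build_target_index(targets: Mapping[str, TargetRegion]) -> dict[str, IntervalTree]:
    """Point-lookup index: chromosome -> IntervalTree whose payloads are
    gene ids. A position may map to several genes (shared loci)."""
    index: dict[str, IntervalTree] = {}
    for gene_id, tr in targets.items():
        for s, e in tr.regions.pairs():
            index.setdefault(tr.regions.chrom, IntervalTree()).addi(s, e, gene_id)
    return index


def genes_at(index: Mapping[str, IntervalTree], chrom: str, pos: int) -> tuple[str, ...]:
    tree = index.get(chrom)
    if tree is None:
        return ()
    return tuple(sorted(iv.data for iv in tree.at(pos)))


def classify_variant(
    variant,
    all_cds: Mapping[str, IntervalSet],
    target_index: Mapping[str, IntervalTree],
    chrom_lengths: Mapping[str, int],
) -> tuple[str, tuple[str, ...]]:
    """Assign exactly one functional class to a somatic variant.

    ``coding`` if any affected reference base overlaps any gene's CDS
    (for deletions, any deleted base; insertions sit at their anchor
    base). Otherwise ``noncoding_target`` with the ids of *all* genes
    whose target region contains the variant's first affected base
    (multi-assignment across a shared locus is intended), else
    ``noncoding_other``.
    """
    chrom = variant.chrom
    if chrom not in chrom_lengths:
        raise RegionError(f"unknown chromosome {chrom!r}")
    a0, a1 = variant.affected_span
    cds = all_cds.get(chrom)
    if cds is not None and cds.overlaps_span(a0, a1):
        return CODING, ()
    genes = genes_at(target_index, chrom, a0)
    if genes:
        return NONCODING_TARGET, genes
    return NONCODING_OTHER, ()


# ---------------------------------------------------------------------
# Sequence composition
# ---------------------------------------------------------------------

_GC = frozenset("GCgc")
_ACGT = frozenset("ACGTacgt")


def gc_fraction(regions: IntervalSet, seq_by_chrom: Mapping[str, str]) -> float:
    """(#G + #C) / (#A + #C + #G + #T) over the region's bases.

    Ambiguous bases (N etc.) are excluded from the denominator. Returns
    NaN for an empty region or an all-ambiguous one.
    """
    if regions.is_empty:
        return float("nan")
    seq = seq_by_chrom[regions.chrom]
    gc = 0
    acgt = 0
    for s, e in regions.pairs():
        chunk = seq[s:e]
        for b in ("G", "C", "g", "c"):
            gc += chunk.count(b)
        for b in ("A", "T", "a", "t"):
            acgt += chunk.count(b)
    acgt += gc
    if acgt == 0:
        return float("nan")
    return gc / acgt
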