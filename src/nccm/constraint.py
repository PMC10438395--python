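"""Evolutionary-constraint scoring and NCCM calling.

A per-base constraint track (phyloP-style, range -20..+9: negative means
accelerated, positive means conserved) drives a single cutoff. In
``fixed`` mode the cutoff is given directly (default 1.2, the value that
corresponds to the top 8% most constrained positions of the 240-mammal
track); in ``percentile`` mode it is calibrated from the track so that
the fraction of scored positions at or above the cutoff is at most the
configured constrained fraction.

A noncoding constraint mutation (NCCM) is a variant that (a) falls in a
gene's noncoding target region and (b) carries a constraint score at or
above the cutoff. Both conditions are inclusive at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .region_model import NONCODING_TARGET, classify_variant

SCORE_MIN = -20.0
SCORE_MAX = 9.0
DEFAULT_FIXED_CUTOFF = 1.2
DEFAULT_CONSTRAINED_FRACTION = 0.08

#: Indel scoring policies: score at the first affected base, or the
#: maximum over the affected span (flanking-base max for insertions).
INDEL_POLICIES = ("max_span", "first_base")


class TrackError(ValueError):
    """Raised for malformed or out-of-range constraint tracks."""


class ConstraintTrack:
    """Per-base constraint scores, one dense float32 array per
    chromosome, NaN marking unscored positions (missing is distinct
    from a score of 0)."""

    def __init__(self, scores: Mapping[str, np.ndarray]):
        self._scores: dict[str, np.ndarray] = {}
        for chrom, arr in scores.items():
            arr = np.asarray(arr, dtype=np.float32)
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < SCORE_MIN or finite.max() > SCORE_MAX):
                raise TrackError(
                    f"{chrom}: scores outside [{SCORE_MIN}, {SCORE_MAX}]"
                )
            self._scores[chrom] = arr

    @classmethod
    def from_records(
        cls,
        chrom_lengths: Mapping[str, int],
        records: Iterable[tuple[str, int, int, float]],
    ) -> "ConstraintTrack":
        """Build from (chrom, start, end, score) half-open records.
        Overlapping records are ambiguous and rejected; positions beyond
        the chromosome length are an error."""
        arrays = {
            c: np.full(int(n), np.nan, dtype=np.float32)
            for c, n in chrom_lengths.items()
        }
        for chrom, start, end, score in records:
            if chrom not in arrays:
                raise TrackError(f"unknown chromosome {chrom!r} in track")
            arr = arrays[chrom]
            if start < 0 or end > len(arr) or start >= end:
                raise TrackError(
                    f"{chrom}:{start}-{end} outside chromosome of length {len(arr)}"
                )
            if np.any(~np.isnan(arr[start:end])):
                raise TrackError(f"overlapping track records at {chrom}:{start}-{end}")
            arr[start:end] = score
        return cls(arrays)

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._scores)

    def array(self, chrom: str) -> np.ndarray:
        return self._scores[chrom]

    def score_at(self, chrom: str, pos: int) -> float:
        """Score at a 0-based position; NaN if unscored or out of range."""
        arr = self._scores.get(chrom)
        if arr is None or pos < 0 or pos >= len(arr):
            return float("nan")
        return float(arr[pos])

    def window_max(self, chrom: str, start: int, end: int) -> float:
        """Max score over [start, end); NaN if nothing scored there."""
        arr = self._scores.get(chrom)
        if arr is None:
            return float("nan")
        chunk = arr[max(0, start) : max(0, end)]
        if chunk.size == 0 or np.all(np.isnan(chunk)):
            return float("nan")
        return float(np.nanmax(chunk))

    def scored_values(self) -> np.ndarray:
        parts = [a[~np.isnan(a)] for a in self._scores.values()]
        if not parts:
            return np.empty(0, dtype=np.float32)
        return np.concatenate(parts)

    @property
    def n_scored(self) -> int:
        return int(sum(np.count_nonzero(~np.isnan(a)) for a in self._scores.values()))


@dataclass(frozen=True)
class ConstraintConfig:
    """Cutoff policy. Exactly one mode is active; ``fixed`` reproduces
    the published parameterisation, ``percentile`` is the general
    method."""

    mode: str = "fixed"  # {"fixed", "percentile"}
    fixed_cutoff: float = DEFAULT_FIXED_CUTOFF
    constrained_fraction: float = DEFAULT_CONSTRAINED_FRACTION
    indel_policy: str = "max_span"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "percentile"):
            raise ValueError(f"unknown cutoff mode {self.mode!r}")
        if not 0.0 < self.constrained_fraction < 1.0:
            raise ValueError("constrained_fraction must be in (0, 1)")
        if self.indel_policy not in INDEL_POLICIES:
            raise ValueError(f"unknown indel policy {self.indel_policy!r}")

    def resolve_cutoff(self, track: ConstraintTrack | None = None) -> float:
        if self.mode == "fixed":
            return float(self.fixed_cutoff)
        if track is None:
            raise ValueError("percentile mode needs a constraint track")
        return calibrate_cutoff(track, self.constrained_fraction)


def calibrate_cutoff(track, fraction: float) -> float:
    """Smallest score c such that the fraction of scored positions with
    score >= c is at most ``fraction``.

    Computed over scored positions only. With heavy ties the realised
    fraction may fall below the requested one (the inclusive >= rule
    keeps calls conservative); in the fully tied degenerate case the
    returned cutoff exceeds every score and nothing passes.
    """
    if isinstance(track, ConstraintTrack):
        scores = track.scored_values()
    else:
        scores = np.asarray(track)
        if scores.dtype.kind != "f":
            scores = scores.astype(np.float64)
        scores = scores[~np.isnan(scores)]
    n = scores.size
    if n == 0:
        raise TrackError("cannot calibrate a cutoff on an empty track")
    m = int(math.floor(fraction * n))  # max positions allowed to pass
    up = scores.dtype.type(np.inf)  # nextafter within the track's dtype
    if m == 0:
        return float(np.nextafter(scores.max(), up))
    t = np.partition(scores, n - m)[n - m]
    if np.count_nonzero(scores >= t) <= m:
        return float(t)
    greater = scores[scores > t]
    if greater.size:
        return float(greater.min())
    return float(np.nextafter(t, up))


# ---------------------------------------------------------------------
# Variant scoring and NCCM calls
# ---------------------------------------------------------------------


def score_variant(variant, track: ConstraintTrack, indel_policy: str = "max_span") -> float:
    """Constraint score for one variant; NaN when unscored.

    ``max_span`` policy: SNVs take the score at their base, MNVs and
    deletions the maximum over the affected reference bases, insertions
    the maximum of the two bases flanking the insertion point.
    ``first_base`` scores every type at its first affected base.
    """
    if indel_policy not in INDEL_POLICIES:
        raise ValueError(f"unknown indel policy {indel_policy!r}")
    a0, a1 = variant.affected_span
    if indel_policy == "first_base" or variant.var_type == "SNV":
        return track.score_at(variant.chrom, a0)
    if variant.var_type == "INS":
        # anchor base and the base just after the insertion point
        return track.window_max(variant.chrom, a0, a0 + 2)
    return track.window_max(variant.chrom, a0, a1)


@dataclass(frozen=True)
class AnnotatedVariant:
    """A somatic call with its constraint score, functional class, gene
    assignments and NCCM flag."""

    variant: object
    score: float
    functional_class: str
    gene_assignments: tuple[str, ...]
    is_nccm: bool = False

    # convenience pass-throughs
    @property
    def sample_id(self) -> str:
        return self.variant.sample_id

    @property
    def chrom(self) -> str:
        return self.variant.chrom

    @property
    def pos(self) -> int:
        return self.variant.pos

    @property
    def var_type(self) -> str:
        return self.variant.var_type


def annotate_variants(
    variants: Sequence,
    all_cds: Mapping,
    target_index: Mapping,
    chrom_lengths: Mapping[str, int],
    track: ConstraintTrack,
    indel_policy: str = "max_span",
) -> list[AnnotatedVariant]:
    """Classify and score every variant (NCCM flags left False; apply
    :func:`call_nccms` with a cutoff)."""
    out = []
    for v in variants:
        cls, genes = classify_variant(v, all_cds, target_index, chrom_lengths)
        s = score_variant(v, track, indel_policy)
        out.append(AnnotatedVariant(v, s, cls, genes))
    return out


def call_nccms(
    annotated: Sequence[AnnotatedVariant], cutoff: float
) -> list[AnnotatedVariant]:
    """Set the NCCM flag: noncoding-target class AND a present score at
    or above the cutoff (inclusive). Idempotent."""
    out = []
    for av in annotated:
        flag = (
            av.functional_class == NONCODING_TARGET
            and not math.isnan(av.score)
            and av.score >= cutoff
        )
        out.append(replace(av, is_nccm=flag))
    return out


def nccms_only(annotated: Sequence[AnnotatedVariant]) -> list[AnnotatedVariant]:
    return [av for av in annotated if av.is_nccm]
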