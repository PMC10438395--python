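"""Synthetic two-cohort study generator.

Produces a complete, self-consistent toy study -- reference genome, gene
models, per-base constraint track, annotation tracks, per-sample somatic
calls, sample metadata, per-mutation signature labels, and a truth
ledger -- with the statistical structure the burden analysis assumes:

* per-sample mutation counts are negative-binomial, with the MB-like
  cohort far more mutated than the PA-like one;
* the constraint track is a two-component Gaussian mixture whose
  high-scoring component occupies a configurable fraction of positions
  (default 8%, mirroring the constrained share of the mammalian genome);
* planted driver genes receive extra noncoding mutations at
  constraint-passing positions of their target regions, at a configured
  cohort-aggregate rate, optionally restricted to a molecular subgroup
  or age stratum;
* each mutation carries a signature label drawn from a class-dependent
  profile, emulating the clock-like signature shift between coding and
  noncoding-constraint mutations.

Background mutations are uniform over the genome: the study design
treats regional rate variation as a confounder to be tested for, and a
uniform null keeps expectations analytic. A per-chromosome rate
multiplier exists for confounder experiments. Signature labels are
drawn directly (no trinucleotide modelling): only the per-class
proportions matter downstream.

All randomness flows from one seed through named substreams, so
identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constraint import (
    ConstraintTrack,
    calibrate_cutoff,
    score_variant,
    SCORE_MIN,
    SCORE_MAX,
)
from .genome_io import (
    ChromosomeTable,
    SomaticVariant,
    write_fasta,
    write_bedgraph,
    write_feature_track,
    write_gene_models_bed12,
    write_tsv,
    write_vcf,
)
from .region_model import (
    GeneModel,
    IntervalSet,
    TargetRegion,
    build_all_targets,
    build_target_index,
    genes_at,
    union_cds,
    DEFAULT_FLANK_BP,
)

CLASS_CODING = "coding"
CLASS_NCCM = "nccm"
CLASS_NONCONSTRAINT = "noncoding_nonconstraint"

#: Default class-dependent signature profiles. The NCCM class is
#: depleted for the clock-like SBS1 and enriched for SBS5 relative to
#: coding mutations -- the direction of the shift the analysis tests.
DEFAULT_SIGNATURE_PROFILES: dict[str, dict[str, float]] = {
    CLASS_CODING: {"SBS1": 0.45, "SBS5": 0.35, "SBS8": 0.10, "SBS18": 0.10},
    CLASS_NCCM: {"SBS1": 0.12, "SBS5": 0.58, "SBS8": 0.15, "SBS18": 0.15},
    CLASS_NONCONSTRAINT: {"SBS1": 0.25, "SBS5": 0.45, "SBS8": 0.15, "SBS18": 0.15},
}


class ConfigError(ValueError):
    """Raised for infeasible or inconsistent simulation parameters."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG: the stream depends only on the
    top-level seed and the stage name."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class AgeModel:
    """Bimodal age-at-diagnosis model: truncated-normal pediatric and
    adult modes mixed by an adult fraction, optionally overridden per
    molecular subgroup (the SHH subgroup is famously bimodal with a
    large adult share)."""

    pediatric_mean: float = 8.0
    pediatric_sd: float = 4.0
    adult_mean: float = 30.0
    adult_sd: float = 8.0
    adult_fraction: float = 0.15
    adult_fraction_by_subgroup: Mapping[str, float] = field(default_factory=dict)

    def draw(self, rng: np.random.Generator, subgroup: str) -> float:
        p_adult = self.adult_fraction_by_subgroup.get(subgroup, self.adult_fraction)
        if rng.random() < p_adult:
            return float(np.clip(rng.normal(self.adult_mean, self.adult_sd), 18.0, 90.0))
        return float(np.clip(rng.normal(self.pediatric_mean, self.pediatric_sd), 0.5, 17.5))


@dataclass(frozen=True)
class PlantedDriver:
    """Truth-ledger entry: a gene given extra noncoding constraint
    mutations at ``target_nccm_rate`` per 100 kbp (cohort-aggregate),
    optionally restricted to one subgroup or age stratum."""

    gene_id: str
    target_nccm_rate: float
    restricted_to: str | None = None  # subgroup label, "pediatric", "adult", or None

    def __post_init__(self) -> None:
        if self.target_nccm_rate <= 0:
            raise ConfigError(f"driver {self.gene_id}: target rate must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    name: str
    n_samples: int
    mutations_mean: float
    mutations_dispersion: float = 2.0
    subgroup_proportions: Mapping[str, float] = field(default_factory=lambda: {"NA": 1.0})
    age_model: AgeModel = field(default_factory=AgeModel)
    planted_drivers: tuple[PlantedDriver, ...] = ()
    signature_profiles: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_SIGNATURE_PROFILES
    )

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError(f"cohort {self.name}: n_samples must be >= 1")
        tot = sum(self.subgroup_proportions.values())
        if abs(tot - 1.0) > 1e-6:
            raise ConfigError(f"cohort {self.name}: subgroup proportions sum to {tot}")
        for cls, prof in self.signature_profiles.items():
            if abs(sum(prof.values()) - 1.0) > 1e-6:
                raise ConfigError(f"cohort {self.name}: signature profile {cls} not normalised")


def default_mb_cohort(planted_drivers: tuple[PlantedDriver, ...] = ()) -> CohortSpec:
    """MB-like cohort: 146 samples, ~1,400 mutations/sample, the four
    molecular subgroups in study proportions (3 WNT / 37 SHH / 43 group 3
    / 60 group 4, 3 unclassified), SHH with a large adult share."""
    return CohortSpec(
        name="MB",
        n_samples=146,
        mutations_mean=1400.0,
        mutations_dispersion=2.0,
        subgroup_proportions={
            "WNT": 3 / 146, "SHH": 37 / 146, "Group3": 43 / 146,
            "Group4": 60 / 146, "NA": 3 / 146,
        },
        age_model=AgeModel(adult_fraction=0.10,
                           adult_fraction_by_subgroup={"WNT": 0.3, "SHH": 0.6}),
        planted_drivers=planted_drivers,
    )


def default_pa_cohort(planted_drivers: tuple[PlantedDriver, ...] = ()) -> CohortSpec:
    """PA-like cohort: 89 samples, few mutations, no molecular subgroups."""
    return CohortSpec(
        name="PA",
        n_samples=89,
        mutations_mean=300.0,
        mutations_dispersion=2.0,
        subgroup_proportions={"NA": 1.0},
        age_model=AgeModel(adult_fraction=0.06),
        planted_drivers=planted_drivers,
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 1_000_000
    n_genes: int = 60
    gene_span_bp_range: tuple[int, int] = (8_000, 20_000)
    exons_per_gene_range: tuple[int, int] = (2, 6)
    constrained_fraction: float = 0.08
    background_score: tuple[float, float] = (0.0, 1.0)  # mean, sd
    constrained_score: tuple[float, float] = (3.0, 0.5)  # mean, sd
    constrained_score_floor: float | None = None  # optional truncation from below
    cohorts: tuple[CohortSpec, ...] = field(
        default_factory=lambda: (default_mb_cohort(), default_pa_cohort())
    )
    repeat_fraction: float = 0.10
    dnase_fraction: float = 0.20
    h3k4me3_fraction: float = 0.10
    feature_constrained_enrichment: float = 0.5
    gc_target: float = 0.41
    flank_bp: int = DEFAULT_FLANK_BP
    indel_fraction: float = 0.0
    min_gene_gap_bp: int = 200
    concentrate_fraction: float = 0.0  # fraction of driver genes planted 2-per-patient
    regional_rate_multipliers: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.constrained_fraction < 1.0:
            raise ConfigError("constrained_fraction must be in [0, 1)")
        for name in ("n_chromosomes", "chrom_length_bp", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.gene_span_bp_range[0] > self.gene_span_bp_range[1]:
            raise ConfigError("bad gene_span_bp_range")
        if self.gene_span_bp_range[1] >= self.chrom_length_bp:
            raise ConfigError("gene spans do not fit on chromosomes")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ConfigError("gc_target must be a proportion")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))


# ---------------------------------------------------------------------
# Reference and gene models
# ---------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_reference(config: SimulationConfig) -> tuple[dict[str, str], ChromosomeTable]:
    """I.i.d. bases at the configured GC target; deterministic per seed."""
    rng = substream(config.seed, "reference")
    gc = config.gc_target
    cum = np.cumsum([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs = {}
    chunk = 1 << 24  # bounded temporaries on large genomes
    for chrom in config.chrom_names:
        parts = []
        remaining = config.chrom_length_bp
        while remaining > 0:
            n = min(chunk, remaining)
            codes = np.searchsorted(cum, rng.random(n), side="right")
            parts.append(_BASES[np.minimum(codes, 3)].tobytes())
            remaining -= n
        seqs[chrom] = b"".join(parts).decode("ascii")
    return seqs, ChromosomeTable.from_sequences(seqs)


_EDGE_MARGIN = 1_000
_MIN_GAP = 200
_MIN_EXON = 150
_MIN_INTRON = 100


_INTRON_WEIGHT = 30.0  # introns dwarf exons, as in real gene anatomy


def _make_exons(rng, chrom, start, end, k):
    span = end - start
    k = max(1, min(k, (span + _MIN_INTRON) // (_MIN_EXON + _MIN_INTRON)))
    if k == 1:
        return IntervalSet.from_pairs(chrom, [(start, end)])
    need = k * _MIN_EXON + (k - 1) * _MIN_INTRON
    slack = span - need
    w = np.concatenate([rng.random(k), rng.random(k - 1) * _INTRON_WEIGHT])
    alloc = np.floor(w / w.sum() * slack).astype(int)
    alloc[k] += slack - alloc.sum()  # residual into the first intron
    pairs = []
    cur = start
    for i in range(k):
        pairs.append((cur, cur + _MIN_EXON + int(alloc[i])))
        cur = pairs[-1][1]
        if i < k - 1:
            cur += _MIN_INTRON + int(alloc[k + i])
    return IntervalSet.from_pairs(chrom, pairs)


def simulate_gene_models(
    config: SimulationConfig, chrom_table: ChromosomeTable
) -> list[GeneModel]:
    """Pack non-overlapping genes onto the chromosomes; every multi-exon
    gene has UTR on both sides, and each chromosome with >= 2 genes has
    at least one pair within 100 kbp (to exercise shared-locus
    assignment)."""
    rng = substream(config.seed, "genes")
    names = list(chrom_table.names)
    lengths = np.array([chrom_table[c] for c in names], dtype=float)
    # largest-remainder apportionment of genes to chromosomes by length
    quota = lengths / lengths.sum() * config.n_genes
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts))[: config.n_genes - counts.sum()]:
        counts[i] += 1
    genes: list[GeneModel] = []
    gid = 0
    lo_span, hi_span = config.gene_span_bp_range
    for chrom, k in zip(names, counts):
        if k == 0:
            continue
        L = chrom_table[chrom]
        min_gap = max(_MIN_GAP, config.min_gene_gap_bp)
        spans = rng.integers(lo_span, hi_span + 1, size=k)
        need = 2 * _EDGE_MARGIN + int(spans.sum()) + (k - 1) * min_gap
        slack = L - need
        if slack < 0:
            raise ConfigError(
                f"{chrom}: cannot pack {k} genes of up to {hi_span} bp into {L} bp"
            )
        w = rng.random(k + 1)
        gaps = np.floor(w / w.sum() * slack).astype(int)
        if k >= 2:  # force an adjacent pair (< 100 kbp span distance)
            surplus = max(0, int(gaps[1]) - 4_000)
            gaps[1] -= surplus
            gaps[-1] += surplus
        cur = _EDGE_MARGIN + int(gaps[0])
        for j in range(k):
            start, end = cur, cur + int(spans[j])
            n_ex = int(rng.integers(config.exons_per_gene_range[0],
                                    config.exons_per_gene_range[1] + 1))
            exons = _make_exons(rng, chrom, start, end, n_ex)
            first_s, first_e = exons.pairs()[0]
            last_s, last_e = exons.pairs()[-1]
            m5 = int(rng.integers(50, max(51, min(400, first_e - first_s))))
            m3 = int(rng.integers(50, max(51, min(400, last_e - last_s))))
            thick_s, thick_e = first_s + m5, last_e - m3
            cds = exons.clip(thick_s, thick_e)
            gene_id = f"G{gid:05d}"
            gid += 1
            genes.append(GeneModel(gene_id=gene_id, chrom=chrom, tx_start=start,
                                   tx_end=end, exons=exons, cds=cds,
                                   symbol=gene_id, strand="+" if rng.random() < 0.5 else "-"))
            cur = end + min_gap + int(gaps[j + 1])
    return genes


# ---------------------------------------------------------------------
# Constraint track and feature tracks
# ---------------------------------------------------------------------


def simulate_constraint_track(
    config: SimulationConfig, chrom_table: ChromosomeTable
) -> tuple[ConstraintTrack, float]:
    """Two-component Gaussian mixture, clipped to the track's score
    range [-20, +9]. Returns the track and the realised fraction of
    positions drawn from the constrained component."""
    b_mean, b_sd = config.background_score
    c_mean, c_sd = config.constrained_score
    if config.constrained_fraction > 0 and c_mean - b_mean < 2 * max(b_sd, c_sd):
        warnings.warn(
            "constrained and background score components overlap heavily; "
            "percentile calibration will be imprecise", stacklevel=2,
        )
    rng = substream(config.seed, "track")
    arrays = {}
    n_constrained = 0
    n_total = 0
    chunk = 1 << 24  # bounded temporaries on large genomes
    for chrom in chrom_table.names:
        L = chrom_table[chrom]
        scores = np.empty(L, dtype=np.float32)
        for off in range(0, L, chunk):
            n = min(chunk, L - off)
            mask = rng.random(n) < config.constrained_fraction
            part = rng.normal(b_mean, b_sd, size=n).astype(np.float32)
            k = int(mask.sum())
            if k:
                draws = rng.normal(c_mean, c_sd, size=k).astype(np.float32)
                if config.constrained_score_floor is not None:
                    draws = np.maximum(draws, np.float32(config.constrained_score_floor))
                part[mask] = draws
            np.clip(part, SCORE_MIN, SCORE_MAX, out=part)
            scores[off:off + n] = part
            n_constrained += k
        arrays[chrom] = scores
        n_total += L
    return ConstraintTrack(arrays), n_constrained / n_total


def _simulate_feature(rng, chrom_table, fraction, track, cutoff, enrichment):
    """Random intervals until the requested genome fraction is covered;
    a share of intervals is centred on constraint-passing positions to
    emulate regulatory enrichment at conserved sites."""
    out = {}
    for chrom in chrom_table.names:
        L = chrom_table[chrom]
        target_bp = int(fraction * L)
        hot = None
        if track is not None and enrichment > 0:
            hot = np.flatnonzero(track.array(chrom) >= cutoff)
        pairs = []
        covered = 0
        while covered < target_bp:
            width = int(rng.integers(200, 1_000))
            if hot is not None and hot.size and rng.random() < enrichment:
                center = int(hot[rng.integers(hot.size)])
                s = max(0, center - width // 2)
            else:
                s = int(rng.integers(0, max(1, L - width)))
            e = min(L, s + width)
            pairs.append((s, e))
            covered += e - s  # approximate; merged below
        out[chrom] = IntervalSet.from_pairs(chrom, pairs)
    return out


def simulate_feature_tracks(
    config: SimulationConfig,
    chrom_table: ChromosomeTable,
    track: ConstraintTrack | None = None,
    cutoff: float | None = None,
) -> dict[str, dict[str, IntervalSet]]:
    rng = substream(config.seed, "features")
    enrich = config.feature_constrained_enrichment
    c = cutoff if cutoff is not None else 0.0
    return {
        "repeats": _simulate_feature(rng, chrom_table, config.repeat_fraction, None, c, 0.0),
        "dnase": _simulate_feature(rng, chrom_table, config.dnase_fraction, track, c, enrich),
        "h3k4me3": _simulate_feature(rng, chrom_table, config.h3k4me3_fraction, track, c, enrich),
    }


# ---------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------


@dataclass
class CohortTruth:
    """Ledger of what was planted, for recovery testing."""

    planted_drivers: dict[str, list[PlantedDriver]]  # cohort -> drivers
    per_sample_counts: dict[str, int]
    cutoff_used: float
    planted_mutations: list[dict] = field(default_factory=list)


@dataclass
class StudyData:
    """Everything one simulation run produced, in memory."""

    config: SimulationConfig
    reference: dict[str, str]
    chrom_table: ChromosomeTable
    genes: list[GeneModel]
    track: ConstraintTrack
    realized_constrained_fraction: float
    targets: dict[str, TargetRegion]
    features: dict[str, dict[str, IntervalSet]]
    variants: list[SomaticVariant]
    metadata: pd.DataFrame
    signatures: pd.DataFrame
    truth: CohortTruth
    cutoff: float


def background_mutations_for_rate(
    rate_per_100kbp: float, genome_bp: int, constrained_fraction: float
) -> int:
    """Total uniform background mutations that give each gene an
    expected in-target constraint-mutation rate of ``rate_per_100kbp``
    (cohort-aggregate): rate = M * fraction * 1e5 / genome_bp."""
    return int(round(rate_per_100kbp * genome_bp / (constrained_fraction * 1e5)))


def _draw_positions(rng, chrom_table, n, multipliers=None):
    names = list(chrom_table.names)
    lengths = np.array([chrom_table[c] for c in names], dtype=float)
    w = lengths.copy()
    if multipliers:
        w *= np.array([multipliers.get(c, 1.0) for c in names])
    w /= w.sum()
    chrom_idx = rng.choice(len(names), size=n, p=w)
    pos = rng.integers(0, lengths[chrom_idx].astype(np.int64))
    return [(names[i], int(p)) for i, p in zip(chrom_idx, pos)]


_OTHER = {
    "A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG",
}


def _make_variant(rng, sample, chrom, pos0, reference, indel_fraction):
    seq = reference[chrom]
    ref = seq[pos0]
    if indel_fraction > 0 and rng.random() < indel_fraction and pos0 + 1 < len(seq):
        if rng.random() < 0.5:  # deletion of one base
            return SomaticVariant(sample, chrom, pos0 + 1, seq[pos0:pos0 + 2], ref)
        ins = _OTHER[ref][rng.integers(3)]
        return SomaticVariant(sample, chrom, pos0 + 1, ref, ref + ins)
    alt = _OTHER[ref][rng.integers(3)]
    return SomaticVariant(sample, chrom, pos0 + 1, ref, alt)


def _eligible_driver_positions(target: TargetRegion, track, cutoff):
    pos = []
    chrom = target.regions.chrom
    arr = track.array(chrom)
    for s, e in target.regions.pairs():
        hits = np.flatnonzero(arr[s:e] >= cutoff)
        pos.extend((s + hits).tolist())
    return np.asarray(pos, dtype=np.int64)


def _stratum_samples(meta_rows: pd.DataFrame, restricted_to: str | None):
    if restricted_to is None:
        return list(meta_rows["sample_id"])
    if restricted_to == "pediatric":
        sel = meta_rows["age_years"] < 18.0
    elif restricted_to == "adult":
        sel = meta_rows["age_years"] >= 18.0
    else:
        sel = meta_rows["subgroup"] == restricted_to
    return list(meta_rows.loc[sel, "sample_id"])


def simulate_cohort(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    track: ConstraintTrack,
    reference: Mapping[str, str],
    cutoff: float | None = None,
) -> StudyData:
    """Simulate every cohort in the configuration against one shared
    genome, track and gene set. See the module docstring for the
    generative model."""
    chrom_table = ChromosomeTable.from_sequences(reference)
    if cutoff is None:
        cutoff = calibrate_cutoff(track, config.constrained_fraction) \
            if config.constrained_fraction > 0 else float("inf")
    gene_ids = {g.gene_id for g in genes}
    all_cds = union_cds(genes)
    targets = build_all_targets(genes, config.flank_bp, chrom_table)
    index = build_target_index(targets)

    meta_rows = []
    variants: list[SomaticVariant] = []
    sig_rows = []
    truth = CohortTruth(planted_drivers={}, per_sample_counts={}, cutoff_used=float(cutoff))

    for cohort in config.cohorts:
        rng = substream(config.seed, f"cohort:{cohort.name}")
        labels = sorted(cohort.subgroup_proportions)
        probs = np.array([cohort.subgroup_proportions[l] for l in labels])
        cohort_meta = []
        for i in range(cohort.n_samples):
            sid = f"{cohort.name}_{i:04d}"
            sg = labels[int(rng.choice(len(labels), p=probs))]
            age = cohort.age_model.draw(rng, sg)
            cohort_meta.append(dict(sample_id=sid, cohort=cohort.name,
                                    subgroup=sg, age_years=round(age, 1)))
        cohort_meta_df = pd.DataFrame(cohort_meta)
        meta_rows.extend(cohort_meta)

        # background mutations, uniform over the genome
        disp = cohort.mutations_dispersion
        p_nb = disp / (disp + cohort.mutations_mean)
        counts = rng.negative_binomial(disp, p_nb, size=cohort.n_samples)
        cohort_variants: list[SomaticVariant] = []
        for row, n_mut in zip(cohort_meta, counts):
            for chrom, pos0 in _draw_positions(rng, chrom_table, int(n_mut),
                                               config.regional_rate_multipliers):
                cohort_variants.append(_make_variant(rng, row["sample_id"], chrom,
                                                     pos0, reference, config.indel_fraction))

        # planted drivers
        truth.planted_drivers[cohort.name] = list(cohort.planted_drivers)
        for k, driver in enumerate(cohort.planted_drivers):
            if driver.gene_id not in gene_ids:
                raise ConfigError(f"planted driver {driver.gene_id} not in gene models")
            target = targets[driver.gene_id]
            if target.length_bp == 0:
                raise ConfigError(f"driver gene {driver.gene_id} has an empty target region")
            eligible = _eligible_driver_positions(target, track, cutoff)
            if eligible.size == 0:
                raise ConfigError(
                    f"driver gene {driver.gene_id}: no constraint-passing positions in target"
                )
            n_plant = int(rng.poisson(driver.target_nccm_rate * target.length_bp / 1e5))
            n_plant = min(n_plant, eligible.size)
            chosen = rng.choice(eligible, size=n_plant, replace=False)
            stratum = _stratum_samples(cohort_meta_df, driver.restricted_to)
            if not stratum:
                raise ConfigError(
                    f"driver gene {driver.gene_id}: stratum {driver.restricted_to!r} "
                    f"has no samples in cohort {cohort.name}"
                )
            order = list(rng.permutation(stratum))
            concentrate = (k < config.concentrate_fraction * len(cohort.planted_drivers))
            for j, pos0 in enumerate(sorted(int(p) for p in chosen)):
                idx = (j // 2) if concentrate else j  # 2-per-patient option
                sample = order[idx % len(order)]
                v = _make_variant(rng, sample, target.regions.chrom, pos0,
                                  reference, 0.0)
                cohort_variants.append(v)
                truth.planted_mutations.append(dict(
                    gene_id=driver.gene_id, sample_id=sample,
                    chrom=v.chrom, pos=v.pos,
                    score=track.score_at(v.chrom, pos0),
                ))

        # per-sample totals and signature labels
        per_sample = cohort_meta_df.set_index("sample_id").index
        tally = {s: 0 for s in per_sample}
        for v in cohort_variants:
            tally[v.sample_id] += 1
        truth.per_sample_counts.update(tally)

        profiles = {c: (sorted(p), np.array([p[s] for s in sorted(p)]))
                    for c, p in cohort.signature_profiles.items()}
        for v in cohort_variants:
            a0, a1 = v.affected_span
            cds = all_cds.get(v.chrom)
            if cds is not None and cds.overlaps_span(a0, a1):
                cls = CLASS_CODING
            else:
                score = score_variant(v, track)
                in_target = bool(genes_at(index, v.chrom, a0))
                cls = CLASS_NCCM if (in_target and not np.isnan(score)
                                     and score >= cutoff) else CLASS_NONCONSTRAINT
            names_, p_ = profiles[cls]
            sig = names_[int(rng.choice(len(names_), p=p_))]
            sig_rows.append(dict(sample_id=v.sample_id, chrom=v.chrom, pos=v.pos,
                                 mutation_class=cls, signature=sig))
        variants.extend(cohort_variants)

    metadata = pd.DataFrame(meta_rows)
    signatures = pd.DataFrame(
        sig_rows, columns=["sample_id", "chrom", "pos", "mutation_class", "signature"]
    )
    return StudyData(
        config=config, reference=dict(reference), chrom_table=chrom_table,
        genes=list(genes), track=track,
        realized_constrained_fraction=float("nan"), targets=targets,
        features={}, variants=variants, metadata=metadata,
        signatures=signatures, truth=truth, cutoff=float(cutoff),
    )


def simulate_study(config: SimulationConfig) -> StudyData:
    """Full generator: reference, genes, track, features, cohorts."""
    reference, chrom_table = simulate_reference(config)
    genes = simulate_gene_models(config, chrom_table)
    track, realized = simulate_constraint_track(config, chrom_table)
    study = simulate_cohort(config, genes, track, reference)
    study.realized_constrained_fraction = realized
    study.features = simulate_feature_tracks(config, chrom_table, track, study.cutoff)
    return study


def simulate_signature_assignments(
    profiles_by_class: Mapping[str, Mapping[str, float]],
    n_per_class: Mapping[str, int],
    rng: np.random.Generator,
    n_samples: int = 20,
) -> pd.DataFrame:
    """Direct draw of a signature-assignment table (no genome needed):
    used to exercise the proportion-shift test at configured effect
    sizes."""
    rows = []
    for cls, n in n_per_class.items():
        names_ = sorted(profiles_by_class[cls])
        p = np.array([profiles_by_class[cls][s] for s in names_])
        draws = rng.choice(len(names_), size=n, p=p)
        samples = rng.integers(0, n_samples, size=n)
        for i, (d, s) in enumerate(zip(draws, samples)):
            rows.append(dict(sample_id=f"S{int(s):03d}", chrom="chr1", pos=i + 1,
                             mutation_class=cls, signature=names_[int(d)]))
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos",
                                       "mutation_class", "signature"])


# ---------------------------------------------------------------------
# Writing a simulated study to disk
# ---------------------------------------------------------------------


def write_truth(path, truth: CohortTruth) -> None:
    payload = dict(
        cutoff_used=truth.cutoff_used,
        planted_drivers={c: [asdict(d) for d in ds]
                         for c, ds in truth.planted_drivers.items()},
        per_sample_counts=truth.per_sample_counts,
        planted_mutations=truth.planted_mutations,
    )
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path) -> CohortTruth:
    payload = json.loads(Path(path).read_text())
    return CohortTruth(
        planted_drivers={c: [PlantedDriver(**d) for d in ds]
                         for c, ds in payload["planted_drivers"].items()},
        per_sample_counts=payload["per_sample_counts"],
        cutoff_used=payload["cutoff_used"],
        planted_mutations=payload["planted_mutations"],
    )


def write_simulation(study: StudyData, out_dir) -> dict[str, object]:
    """Write every external-format artefact of a simulated study; returns
    the path manifest."""
    out = Path(out_dir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    write_fasta(out / "reference.fa", study.reference)
    write_gene_models_bed12(out / "genes.bed", study.genes, out / "genes_cds.bed")
    write_bedgraph(out / "constraint.bedgraph", study.track)
    for name, sets in study.features.items():
        write_feature_track(out / f"{name}.bed", sets)
    by_sample: dict[str, list[SomaticVariant]] = {
        s: [] for s in study.metadata["sample_id"]
    }
    for v in study.variants:
        by_sample[v.sample_id].append(v)
    vcf_paths = []
    for sid in sorted(by_sample):
        p = out / "vcf" / f"{sid}.vcf"
        write_vcf(p, sid, by_sample[sid], study.chrom_table)
        vcf_paths.append(p)
    write_tsv(study.metadata, out / "metadata.tsv")
    write_tsv(study.signatures, out / "signatures.tsv")
    write_truth(out / "truth.json", study.truth)
    return {
        "reference": out / "reference.fa",
        "gene_models": out / "genes.bed",
        "cds_bed": out / "genes_cds.bed",
        "constraint": out / "constraint.bedgraph",
        "features": [out / f"{n}.bed" for n in sorted(study.features)],
        "vcfs": vcf_paths,
        "metadata": out / "metadata.tsv",
        "signatures": out / "signatures.tsv",
        "truth": out / "truth.json",
    }
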