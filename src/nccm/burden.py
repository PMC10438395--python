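"""Per-gene NCCM burden and candidate driver-gene selection.

The burden statistic is deliberately simple: for each gene, the number
of NCCMs assigned to its noncoding target region, normalised to the
target length (per 100 kbp), with a per-patient variant (rate divided by
the cohort's sample count) for cross-cohort comparison. Candidate genes
are selected by two fixed inclusive thresholds -- a rate cutoff
(default >= 2 NCCMs / 100 kbp) and a raw-count cutoff (default >= 5) --
and reported as the rate set, the count set and their union. No
significance test is attached: the thresholds themselves define the
candidate sets.

An NCCM assigned to several genes of a shared locus counts once toward
each of them; reports group such genes into loci (connected components
of genes sharing at least one NCCM position) so the sharing stays
visible, but counts are never deduplicated.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constraint import AnnotatedVariant
from .region_model import GeneModel, TargetRegion


@dataclass
class BurdenTable:
    """Per-gene burden rows plus the per-(gene, sample) count map."""

    table: pd.DataFrame
    per_sample_counts: dict[str, Counter]
    n_samples: int

    def rate_of(self, gene_id: str) -> float:
        row = self.table.loc[self.table["gene_id"] == gene_id]
        return float(row["rate_per_100kbp"].iloc[0])


def compute_gene_burden(
    nccms: Sequence[AnnotatedVariant],
    targets: Mapping[str, TargetRegion],
    n_samples: int,
    genes: Sequence[GeneModel] | None = None,
) -> BurdenTable:
    """One row per gene (zero-NCCM genes included with rate 0).

    An NCCM assigned to k genes contributes 1 to each of the k rows.
    Genes whose target region is empty are kept but flagged: their rate
    is NaN (undefined), not 0.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    info = {g.gene_id: g for g in genes} if genes else {}
    counts: dict[str, Counter] = {gid: Counter() for gid in targets}
    for av in nccms:
        if not av.is_nccm:
            continue
        if not av.gene_assignments:
            raise ValueError("NCCM without a gene assignment")
        for gid in av.gene_assignments:
            if gid in counts:
                counts[gid][av.sample_id] += 1
    rows = []
    for gid in sorted(targets):
        tr = targets[gid]
        n = sum(counts[gid].values())
        L = tr.length_bp
        rate = (n / L * 1e5) if L > 0 else float("nan")
        g = info.get(gid)
        rows.append(dict(
            gene_id=gid,
            symbol=g.symbol if g else gid,
            chrom=tr.regions.chrom if not tr.regions.is_empty else (g.chrom if g else ""),
            nccm_count=n,
            target_len_bp=L,
            rate_per_100kbp=rate,
            rate_per_patient=rate / n_samples if L > 0 else float("nan"),
            max_per_sample=max(counts[gid].values(), default=0),
            zero_target=L == 0,
        ))
    return BurdenTable(pd.DataFrame(rows), counts, n_samples)


@dataclass(frozen=True)
class CandidateSets:
    """Rate-based, count-based and union candidate gene sets, each
    sorted by descending rate then gene id (deterministic ties)."""

    rate_set: tuple[str, ...]
    count_set: tuple[str, ...]
    union_set: tuple[str, ...]


def _sorted_by_rate(df: pd.DataFrame, gene_ids) -> tuple[str, ...]:
    sub = df[df["gene_id"].isin(gene_ids)].copy()
    sub = sub.sort_values(["rate_per_100kbp", "gene_id"],
                          ascending=[False, True], kind="mergesort")
    return tuple(sub["gene_id"])


def select_candidates(
    burden: BurdenTable | pd.DataFrame,
    rate_cutoff: float = 2.0,
    count_cutoff: int = 5,
) -> CandidateSets:
    """Inclusive thresholds: rate >= rate_cutoff, count >= count_cutoff.
    Genes with an undefined rate (empty target) never qualify by rate."""
    df = burden.table if isinstance(burden, BurdenTable) else burden
    rate_ids = set(df.loc[df["rate_per_100kbp"] >= rate_cutoff, "gene_id"])
    count_ids = set(df.loc[df["nccm_count"] >= count_cutoff, "gene_id"])
    return CandidateSets(
        rate_set=_sorted_by_rate(df, rate_ids),
        count_set=_sorted_by_rate(df, count_ids),
        union_set=_sorted_by_rate(df, rate_ids | count_ids),
    )


# ---------------------------------------------------------------------
# Locus grouping
# ---------------------------------------------------------------------


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        p = self.parent.setdefault(x, x)
        if p != x:
            p = self.parent[x] = self.find(p)
        return p

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def locus_groups(nccms: Sequence[AnnotatedVariant],
                 all_genes: Sequence[str] = ()) -> dict[str, str]:
    """Gene -> locus id, where a locus is a connected component of genes
    sharing at least one NCCM. The locus id is the lexicographically
    smallest member. Genes sharing nothing form singleton loci."""
    uf = _UnionFind()
    for gid in all_genes:
        uf.find(gid)
    for av in nccms:
        if not av.is_nccm or len(av.gene_assignments) < 2:
            if av.is_nccm:
                for gid in av.gene_assignments:
                    uf.find(gid)
            continue
        first = av.gene_assignments[0]
        for gid in av.gene_assignments[1:]:
            uf.union(first, gid)
    return {g: uf.find(g) for g in uf.parent}


def per_sample_distribution(
    burden: BurdenTable, candidate_genes: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """For each candidate gene, the maximum NCCM count any single sample
    contributed, and the fraction of candidates where that maximum is 1
    vs >= 2 (the study found most candidates spread one NCCM per
    patient)."""
    rows = []
    for gid in candidate_genes:
        c = burden.per_sample_counts.get(gid, Counter())
        rows.append(dict(gene_id=gid,
                         n_samples_hit=len(c),
                         max_per_sample=max(c.values(), default=0)))
    df = pd.DataFrame(rows, columns=["gene_id", "n_samples_hit", "max_per_sample"])
    if len(df) == 0:
        return df, {"frac_max_one": float("nan"), "frac_max_two_plus": float("nan")}
    summary = {
        "frac_max_one": float((df["max_per_sample"] == 1).mean()),
        "frac_max_two_plus": float((df["max_per_sample"] >= 2).mean()),
    }
    return df, summary


def finalize_burden_table(
    burden: BurdenTable,
    candidates: CandidateSets,
    loci: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Reporting view: burden rows plus candidate-set membership and
    locus id, sorted by descending rate then gene id."""
    df = burden.table.copy()
    df["in_rate_set"] = df["gene_id"].isin(candidates.rate_set)
    df["in_count_set"] = df["gene_id"].isin(candidates.count_set)
    loci = loci or {}
    df["locus_id"] = [loci.get(g, g) for g in df["gene_id"]]
    df = df.sort_values(["rate_per_100kbp", "gene_id"],
                        ascending=[False, True], kind="mergesort", na_position="last")
    cols = ["gene_id", "symbol", "chrom", "nccm_count", "target_len_bp",
            "rate_per_100kbp", "rate_per_patient", "max_per_sample",
            "in_rate_set", "in_count_set", "locus_id", "zero_target"]
    return df[cols].reset_index(drop=True)
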