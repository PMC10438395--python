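"""Stratified NCCM rates, rank correlations, patient coverage, pathway
tallies.

Rates are recomputed per stratum -- molecular subgroup (WNT, SHH,
Group3, Group4) and age group (pediatric < 18 y, adult >= 18 y; age
exactly 18 is adult) -- using only that stratum's samples and its own
sample count as the per-patient denominator. Strata are then compared
gene-by-gene with Kendall's tau-b (tie-corrected: rate vectors are full
of zeros). The WNT stratum is computed but, being tiny in the study
design (n = 3), is excluded from the default correlation matrix by a
minimum-sample-count gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constraint import AnnotatedVariant
from .region_model import TargetRegion

SUBGROUP_ORDER = ("WNT", "SHH", "Group3", "Group4")
AGE_STRATA = ("pediatric", "adult")


@dataclass(frozen=True)
class AgeGroupRule:
    """pediatric: age < pediatric_max_exclusive; adult: age >= it."""

    pediatric_max_exclusive: float = 18.0

    def __post_init__(self) -> None:
        if self.pediatric_max_exclusive <= 0:
            raise ValueError("pediatric_max_exclusive must be > 0")

    def group(self, age_years: float) -> str:
        return "pediatric" if age_years < self.pediatric_max_exclusive else "adult"


@dataclass
class StratifiedRates:
    """Per-(candidate gene, stratum) per-patient NCCM rates. A stratum
    with zero samples yields a NaN column."""

    genes: list[str]
    strata: list[str]
    matrix: np.ndarray  # shape (n_genes, n_strata)
    n_by_stratum: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.strata)
        df.insert(0, "gene_id", self.genes)
        return df

    def column(self, stratum: str) -> np.ndarray:
        return self.matrix[:, self.strata.index(stratum)]


def _strata_samples(metadata: pd.DataFrame, rule: AgeGroupRule) -> dict[str, list[str]]:
    """Stratum -> sample ids. Samples with subgroup NA are excluded from
    subgroup strata but participate in the age strata."""
    out: dict[str, list[str]] = {}
    present = [s for s in SUBGROUP_ORDER if (metadata["subgroup"] == s).any()]
    for s in present:
        out[s] = list(metadata.loc[metadata["subgroup"] == s, "sample_id"])
    ped = metadata["age_years"] < rule.pediatric_max_exclusive
    out["pediatric"] = list(metadata.loc[ped, "sample_id"])
    out["adult"] = list(metadata.loc[~ped, "sample_id"])
    return out


def stratified_rates(
    nccms: Sequence[AnnotatedVariant],
    metadata: pd.DataFrame,
    targets: Mapping[str, TargetRegion],
    candidate_genes: Sequence[str],
    rule: AgeGroupRule = AgeGroupRule(),
) -> StratifiedRates:
    genes = list(candidate_genes)
    strata_samples = _strata_samples(metadata, rule)
    strata = list(strata_samples)
    counts = {(g, s): 0 for g in genes for s in strata}
    sample_strata: dict[str, list[str]] = {}
    for s, ids in strata_samples.items():
        for sid in ids:
            sample_strata.setdefault(sid, []).append(s)
    gene_set = set(genes)
    for av in nccms:
        if not av.is_nccm:
            continue
        for stratum in sample_strata.get(av.sample_id, ()):
            for gid in av.gene_assignments:
                if gid in gene_set:
                    counts[(gid, stratum)] += 1
    matrix = np.full((len(genes), len(strata)), np.nan)
    n_by = {s: len(ids) for s, ids in strata_samples.items()}
    for j, s in enumerate(strata):
        n = n_by[s]
        if n == 0:
            continue
        for i, g in enumerate(genes):
            L = targets[g].length_bp
            matrix[i, j] = counts[(g, s)] / L * 1e5 / n if L > 0 else np.nan
    return StratifiedRates(genes, strata, matrix, n_by)


def kendall_matrix(
    rates: StratifiedRates, min_samples: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise tau-b over the candidate-gene rate vectors; strata with
    fewer than ``min_samples`` samples (e.g. a 3-patient WNT stratum)
    are dropped from the matrix."""
    if len(rates.genes) < 2:
        raise ValueError("need at least 2 genes for a rank correlation")
    keep = [s for s in rates.strata
            if rates.n_by_stratum.get(s, 0) >= min_samples
            and not np.all(np.isnan(rates.column(s)))]
    tau = pd.DataFrame(np.eye(len(keep)), index=keep, columns=keep)
    pval = pd.DataFrame(np.full((len(keep), len(keep)), np.nan), index=keep, columns=keep)
    for i, a in enumerate(keep):
        for j, b in enumerate(keep):
            if j <= i:
                continue
            res = stats.kendalltau(rates.column(a), rates.column(b), variant="b")
            tau.loc[a, b] = tau.loc[b, a] = float(res.statistic)
            pval.loc[a, b] = pval.loc[b, a] = float(res.pvalue)
    return tau, pval


def age_pair_correlations(rates: StratifiedRates) -> dict[str, float]:
    """Both rank and linear correlation for the pediatric/adult pair
    (reported side by side since either convention is defensible for a
    two-stratum scatter)."""
    x, y = rates.column("pediatric"), rates.column("adult")
    ok = ~(np.isnan(x) | np.isnan(y))
    out = {"kendall_tau": float("nan"), "kendall_p": float("nan"),
           "pearson_r": float("nan"), "pearson_p": float("nan")}
    if ok.sum() >= 2:
        kt = stats.kendalltau(x[ok], y[ok], variant="b")
        out["kendall_tau"], out["kendall_p"] = float(kt.statistic), float(kt.pvalue)
        if np.ptp(x[ok]) > 0 and np.ptp(y[ok]) > 0:
            pr = stats.pearsonr(x[ok], y[ok])
            out["pearson_r"], out["pearson_p"] = float(pr.statistic), float(pr.pvalue)
    return out


def patient_coverage(
    nccms: Sequence[AnnotatedVariant],
    metadata: pd.DataFrame,
    candidate_genes: Sequence[str],
    gene_to_locus: Mapping[str, str],
    rule: AgeGroupRule = AgeGroupRule(),
) -> pd.DataFrame:
    """Per stratum (plus 'all'): fraction of samples with >= 1 NCCM in
    any candidate gene, and fraction with NCCMs in >= 2 distinct loci.
    Two NCCMs in one locus count as one locus for a sample."""
    gene_set = set(candidate_genes)
    loci_by_sample: dict[str, set[str]] = {}
    for av in nccms:
        if not av.is_nccm:
            continue
        hit = gene_set.intersection(av.gene_assignments)
        if hit:
            loci = {gene_to_locus.get(g, g) for g in hit}
            loci_by_sample.setdefault(av.sample_id, set()).update(loci)
    strata = {"all": list(metadata["sample_id"])}
    strata.update(_strata_samples(metadata, rule))
    rows = []
    for name, ids in strata.items():
        n = len(ids)
        if n == 0:
            rows.append(dict(stratum=name, n_samples=0,
                             frac_with_nccm=float("nan"),
                             frac_multi_locus=float("nan")))
            continue
        k1 = sum(1 for s in ids if loci_by_sample.get(s))
        k2 = sum(1 for s in ids if len(loci_by_sample.get(s, ())) >= 2)
        rows.append(dict(stratum=name, n_samples=n,
                         frac_with_nccm=k1 / n, frac_multi_locus=k2 / n))
    return pd.DataFrame(rows, columns=["stratum", "n_samples",
                                       "frac_with_nccm", "frac_multi_locus"])


@dataclass(frozen=True)
class GenesetTally:
    set_name: str
    total_nccms: int
    genes_hit: int
    missing_genes: tuple[str, ...]
    per_stratum: pd.DataFrame  # stratum, n_samples, nccm_count, rate_per_patient


def geneset_tally(
    nccms: Sequence[AnnotatedVariant],
    gene_set: Sequence[str],
    metadata: pd.DataFrame,
    known_genes: Sequence[str],
    rule: AgeGroupRule = AgeGroupRule(),
    set_name: str = "geneset",
) -> GenesetTally:
    """NCCM tally for a user-supplied gene list (e.g. a signalling
    pathway): total NCCMs landing in the set, genes hit, and
    per-stratum counts with a per-patient rate. A mutation assigned to
    two set genes counts once. Genes absent from the models are listed,
    not fatal."""
    known = set(known_genes)
    wanted = [g for g in gene_set if g in known]
    missing = tuple(sorted(set(gene_set) - known))
    wanted_set = set(wanted)
    hits = []  # (sample_id, mutation key, genes hit)
    genes_hit: set[str] = set()
    for av in nccms:
        if not av.is_nccm:
            continue
        hit = wanted_set.intersection(av.gene_assignments)
        if hit:
            hits.append((av.sample_id, (av.chrom, av.pos)))
            genes_hit.update(hit)
    strata = {"all": list(metadata["sample_id"])}
    strata.update(_strata_samples(metadata, rule))
    sample_stratum: dict[str, list[str]] = {}
    for s, ids in strata.items():
        for sid in ids:
            sample_stratum.setdefault(sid, []).append(s)
    per: dict[str, int] = {s: 0 for s in strata}
    for sid, _key in hits:
        for s in sample_stratum.get(sid, ()):
            per[s] += 1
    rows = [dict(stratum=s, n_samples=len(strata[s]), nccm_count=per[s],
                 rate_per_patient=per[s] / len(strata[s]) if strata[s] else float("nan"))
            for s in strata]
    return GenesetTally(set_name, len(hits), len(genes_hit), missing,
                        pd.DataFrame(rows, columns=["stratum", "n_samples",
                                                    "nccm_count", "rate_per_patient"]))


def read_gene_sets(path) -> dict[str, list[str]]:
    """Plain text, one gene per line (set name = 'geneset'), or
    two-column TSV (set_name, gene)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                sets.setdefault("geneset", []).append(fields[0])
            else:
                sets.setdefault(fields[0], []).append(fields[1])
    return sets
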