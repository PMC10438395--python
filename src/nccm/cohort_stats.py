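"""Cross-cohort comparison, confounder checks, signature shift tests.

Three questions about the burden signal:

1. Is the per-patient NCCM rate higher in one cohort than another
   (all genes, and each cohort's top 0.5% of genes)? Welch's unequal-
   variance t test.
2. Is the per-gene rate explained by confounders -- gene length, local
   mutation rate, GC content, low-complexity regions? Pearson
   correlations, plus a binomial test of NCCM overlap with repeats
   against the genome-wide expectation.
3. Do mutational-signature proportions shift between mutation classes
   (coding vs NCCM vs noncoding non-constraint)? Fisher's exact test on
   pooled per-class counts, after a two-gate inclusion filter
   (>= 5% of mutations in at least one sample AND present in >= 10% of
   samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constraint import AnnotatedVariant
from .region_model import IntervalSet, TargetRegion, gc_fraction


# ---------------------------------------------------------------------
# Cohort rate comparison
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class CohortComparison:
    cohort_a: str
    cohort_b: str
    n_genes_a: int
    n_genes_b: int
    mean_a: float
    mean_b: float
    t_all: float
    p_all: float
    top_n_a: int
    top_n_b: int
    t_top: float
    p_top: float

    @property
    def direction(self) -> str:
        return f"{self.cohort_a} > {self.cohort_b}" if self.mean_a > self.mean_b \
            else f"{self.cohort_b} > {self.cohort_a}"


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # degenerate zero-variance case scipy leaves as nan: equal constants
    # mean "no difference", so report t=0, p=1
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def compare_cohort_rates(
    burden_a: pd.DataFrame,
    burden_b: pd.DataFrame,
    cohort_a: str = "A",
    cohort_b: str = "B",
    top_fraction: float = 0.005,
    value_col: str = "rate_per_patient",
) -> CohortComparison:
    """Welch t on per-patient rates: all genes, and each cohort's own
    top ``top_fraction`` of genes by rate."""
    xa = burden_a[value_col].dropna().to_numpy(float)
    xb = burden_b[value_col].dropna().to_numpy(float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need at least 2 genes per cohort")
    t_all, p_all = _welch(xa, xb)
    ka = max(1, math.ceil(top_fraction * len(xa)))
    kb = max(1, math.ceil(top_fraction * len(xb)))
    top_a = np.sort(xa)[-ka:]
    top_b = np.sort(xb)[-kb:]
    if ka < 2 or kb < 2:
        t_top, p_top = float("nan"), float("nan")
    else:
        t_top, p_top = _welch(top_a, top_b)
    return CohortComparison(cohort_a, cohort_b, len(xa), len(xb),
                            float(xa.mean()), float(xb.mean()),
                            t_all, p_all, ka, kb, t_top, p_top)


# ---------------------------------------------------------------------
# Confounders
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class ConfounderReport:
    pearson_r_length: float
    pearson_r_local_rate: float
    pearson_r_gc: float
    repeat_overlap_observed: float
    repeat_overlap_expected: float
    repeat_binomial_p: float
    n_top_nccms: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def correlate_confounders(
    burden_df: pd.DataFrame,
    all_variants: Sequence[AnnotatedVariant],
    targets: Mapping[str, TargetRegion],
    gene_spans: Mapping[str, int],
    reference: Mapping[str, str] | None,
    repeats: Mapping[str, IntervalSet],
    genome_bp: int,
    top_genes: Sequence[str],
    nccms: Sequence[AnnotatedVariant],
) -> ConfounderReport:
    """Per-gene confounder correlations against the NCCM rate, plus the
    repeat-region overlap test on the top genes' NCCMs.

    Local mutation rate counts *all* somatic mutations (any class) whose
    first affected base falls in the gene's target region, per bp.
    """
    df = burden_df[burden_df["target_len_bp"] > 0]
    order = list(df["gene_id"])
    rate = df["rate_per_100kbp"].to_numpy(float)

    # local (all-class) mutation counts per gene target
    local = {g: 0 for g in order}
    pos_by_chrom: dict[str, list[int]] = {}
    for av in all_variants:
        pos_by_chrom.setdefault(av.chrom, []).append(av.variant.affected_span[0])
    for g in order:
        tr = targets[g]
        if tr.regions.is_empty:
            continue
        pos = pos_by_chrom.get(tr.regions.chrom)
        if pos:
            local[g] = int(tr.regions.contains(np.asarray(pos)).sum())
    local_rate = np.array([local[g] / targets[g].length_bp for g in order])

    length = np.array([gene_spans[g] for g in order], dtype=float)
    counts = df["nccm_count"].to_numpy(float)
    r_length = _pearson(length, counts)
    r_local = _pearson(local_rate, rate)

    if reference is not None:
        gc = np.array([gc_fraction(targets[g].regions, reference) for g in order])
        ok = ~np.isnan(gc)
        r_gc = _pearson(gc[ok], rate[ok])
    else:
        r_gc = float("nan")

    # repeat-region overlap of top-gene NCCMs vs genome expectation
    top = set(top_genes)
    top_positions = []
    seen = set()
    for av in nccms:
        if av.is_nccm and top.intersection(av.gene_assignments):
            key = (av.chrom, av.variant.affected_span[0])
            if key not in seen:
                seen.add(key)
                top_positions.append(key)
    repeat_bp = sum(s.total_length_bp for s in repeats.values())
    expected = repeat_bp / genome_bp if genome_bp else float("nan")
    n = len(top_positions)
    if n:
        k = sum(
            1 for chrom, p in top_positions
            if chrom in repeats and repeats[chrom].contains_point(p)
        )
        observed = k / n
        p_binom = float(stats.binomtest(k, n, expected).pvalue) \
            if 0.0 < expected < 1.0 else float("nan")
    else:
        observed, p_binom = float("nan"), float("nan")
    return ConfounderReport(r_length, r_local, r_gc, observed, expected, p_binom, n)


# ---------------------------------------------------------------------
# Mutational signatures
# ---------------------------------------------------------------------


def filter_signatures(
    assignments: pd.DataFrame,
    n_samples: int | None = None,
    min_sample_share: float = 0.05,
    min_cohort_fraction: float = 0.10,
) -> list[str]:
    """Retain signature s iff some sample assigns >= 5% of its mutations
    to s AND s appears in >= 10% of samples (both gates inclusive)."""
    if len(assignments) == 0:
        return []
    if n_samples is None:
        n_samples = assignments["sample_id"].nunique()
    per_sample_total = assignments.groupby("sample_id").size()
    per_sig_sample = assignments.groupby(["signature", "sample_id"]).size()
    share = per_sig_sample / per_sample_total
    retained = []
    for sig in sorted(assignments["signature"].unique()):
        shares = share.xs(sig, level="signature")
        gate1 = bool((shares >= min_sample_share).any())
        gate2 = len(shares) >= min_cohort_fraction * n_samples
        if gate1 and gate2:
            retained.append(sig)
    return retained


@dataclass(frozen=True)
class SignatureShift:
    signature: str
    class_a: str
    class_b: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    share_a: float
    share_b: float

    @property
    def direction(self) -> str:
        if self.share_b < self.share_a:
            return f"depleted in {self.class_b}"
        if self.share_b > self.share_a:
            return f"enriched in {self.class_b}"
        return "no shift"


def signature_shift_test(
    assignments: pd.DataFrame,
    signature: str,
    class_a: str = "coding",
    class_b: str = "nccm",
    two_sided_rule: str = "point",
) -> SignatureShift:
    """Fisher's exact test of the 2x2 table
    [[#a with s, #a without], [#b with s, #b without]] over pooled
    per-class mutation counts.

    The default two-sided p sums the probabilities of all tables (fixed
    margins) no more likely than the observed one -- the usual
    point-probability convention; ``two_sided_rule="double"`` doubles
    the smaller one-sided tail instead.
    """
    rows = []
    for cls in (class_a, class_b):
        sub = assignments[assignments["mutation_class"] == cls]
        if len(sub) == 0:
            raise ValueError(f"mutation class {cls!r} has no mutations")
        with_s = int((sub["signature"] == signature).sum())
        rows.append((with_s, len(sub) - with_s))
    table = (tuple(rows[0]), tuple(rows[1]))
    if two_sided_rule == "point":
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    elif two_sided_rule == "double":
        p_less = stats.fisher_exact(table, alternative="less")[1]
        p_greater = stats.fisher_exact(table, alternative="greater")[1]
        p = float(min(1.0, 2.0 * min(p_less, p_greater)))
    else:
        raise ValueError(f"unknown two-sided rule {two_sided_rule!r}")
    odds = float(stats.contingency.odds_ratio(np.asarray(table), kind="conditional").statistic)
    share_a = rows[0][0] / sum(rows[0])
    share_b = rows[1][0] / sum(rows[1])
    return SignatureShift(signature, class_a, class_b, table, odds, p, share_a, share_b)


# ---------------------------------------------------------------------
# Regulatory-annotation overlap
# ---------------------------------------------------------------------


def regulatory_overlap(
    nccms: Sequence[AnnotatedVariant],
    tracks: Mapping[str, Mapping[str, IntervalSet]],
) -> pd.DataFrame:
    """Fraction of NCCM positions falling inside each named merged
    annotation track."""
    positions = [(av.chrom, av.variant.affected_span[0])
                 for av in nccms if av.is_nccm]
    rows = []
    for name in sorted(tracks):
        sets = tracks[name]
        if positions:
            k = sum(1 for chrom, p in positions
                    if chrom in sets and sets[chrom].contains_point(p))
            frac = k / len(positions)
        else:
            frac = 0.0
        rows.append(dict(track=name, n_nccms=len(positions), overlap_fraction=frac))
    return pd.DataFrame(rows, columns=["track", "n_nccms", "overlap_fraction"])
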