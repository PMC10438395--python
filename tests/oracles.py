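"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is deliberately naive -- per-base membership scans,
O(n^2) pair counting, exact integer hypergeometric enumeration -- and
shares no code with the implementation it checks.
"""

from __future__ import annotations

from math import comb, sqrt

import numpy as np


# -- per-base region geometry -----------------------------------------


def cds_mask(genes, chrom: str, chrom_len: int) -> np.ndarray:
    m = np.zeros(chrom_len, dtype=bool)
    for g in genes:
        if g.chrom == chrom:
            for s, e in g.cds.pairs():
                m[s:e] = True
    return m


def target_mask(gene, genes, flank: int, chrom_len: int) -> np.ndarray:
    """Per-base membership of the gene's noncoding target region."""
    m = np.zeros(chrom_len, dtype=bool)
    lo = max(0, gene.tx_start - flank)
    hi = min(chrom_len, gene.tx_end + flank)
    m[lo:hi] = True
    m &= ~cds_mask(genes, gene.chrom, chrom_len)
    return m


def mask_to_pairs(m: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], m, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def classify_oracle(variant, genes, flank: int, chrom_lengths) -> tuple[str, tuple[str, ...]]:
    """Per-base re-derivation of the functional class and gene
    assignments of one variant."""
    L = chrom_lengths[variant.chrom]
    a0, a1 = variant.affected_span
    cds = cds_mask(genes, variant.chrom, L)
    if cds[a0:a1].any():
        return "coding", ()
    hits = []
    for g in genes:
        if g.chrom != variant.chrom:
            continue
        if target_mask(g, genes, flank, L)[a0]:
            hits.append(g.gene_id)
    if hits:
        return "noncoding_target", tuple(sorted(hits))
    return "noncoding_other", ()


def burden_counts_oracle(variants, genes, flank: int, chrom_lengths,
                         track, cutoff: float) -> dict[str, int]:
    """Per-gene NCCM counts by testing every (variant, gene) pair with
    per-base masks and a direct score lookup."""
    counts = {g.gene_id: 0 for g in genes}
    masks = {g.gene_id: target_mask(g, genes, flank, chrom_lengths[g.chrom])
             for g in genes}
    for v in variants:
        cls, hit = classify_oracle(v, genes, flank, chrom_lengths)
        if cls != "noncoding_target":
            continue
        score = oracle_score(v, track)
        if np.isnan(score) or score < cutoff:
            continue
        a0, _ = v.affected_span
        for g in genes:
            if g.chrom == v.chrom and masks[g.gene_id][a0]:
                counts[g.gene_id] += 1
    return counts


def oracle_score(v, track) -> float:
    """Re-derive the max-span scoring policy by explicit lookups."""
    a0, a1 = v.affected_span
    if v.var_type == "SNV":
        return track.score_at(v.chrom, a0)
    if v.var_type == "INS":
        vals = [track.score_at(v.chrom, a0), track.score_at(v.chrom, a0 + 1)]
    else:
        vals = [track.score_at(v.chrom, p) for p in range(a0, a1)]
    vals = [x for x in vals if not np.isnan(x)]
    return max(vals) if vals else float("nan")


# -- statistics --------------------------------------------------------


def kendall_tau_b_naive(x, y) -> float:
    """O(n^2) concordant/discordant pair count with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    denom = sqrt((n0 - ties_x) * (n0 - ties_y))
    if denom == 0:
        return float("nan")
    return (conc - disc) / denom


def fisher_point_two_sided(table) -> float:
    """Exact two-sided Fisher p by full enumeration over tables with the
    observed margins, summing hypergeometric probabilities <= the
    observed table's. Pure integer arithmetic until the final division."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0  # degenerate margin: only one table possible
    num_obs = comb(r1, a) * comb(r2, c)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        num = comb(r1, x) * comb(r2, c1 - x)
        if num <= num_obs:
            total += num
    return total / comb(n, c1)


def pearson_naive(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / sqrt((xm ** 2).sum() * (ym ** 2).sum()))
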