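"""Pipeline orchestration: simulate -> annotate -> burden -> stats ->
subgroups, driven by one config and one seed.

Stages communicate only through files under the run's output directory,
so any downstream stage can be re-run alone from intermediates and
reproduce the full run's outputs. All fixed analysis constants live in
:class:`PipelineConfig`, whose defaults reproduce the published
parameterisation: +-100 kbp flanks, phyloP-style cutoff 1.2 (top 8% in
percentile mode), rate cutoff 2 NCCMs/100 kbp, count cutoff 5, top 0.5%
cohort comparison, pediatric/adult split at 18 y, signature inclusion
gates 5% / 10%.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import burden as burden_mod
from . import cohort_stats, subgroup_analysis
from .constraint import (
    AnnotatedVariant,
    ConstraintConfig,
    annotate_variants,
    call_nccms,
    nccms_only,
)
from .genome_io import (
    ChromosomeTable,
    SomaticVariant,
    read_constraint_track,
    read_fasta,
    read_feature_tracks,
    read_gene_models,
    read_sample_metadata,
    read_signature_assignments,
    read_vcf_cohort,
    write_results,
    write_tsv,
)
from .region_model import build_all_targets, build_target_index, union_cds
from .subgroup_analysis import AgeGroupRule
from .synthetic_cohort import (
    SimulationConfig,
    CohortSpec,
    PlantedDriver,
    AgeModel,
    read_truth,
    simulate_study,
    write_simulation,
)

logger = logging.getLogger("nccm")

STAGES = ("simulate", "annotate", "burden", "stats", "subgroups")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    simulation: SimulationConfig | None = None
    inputs_dir: Path | None = None  # defaults to out_dir/inputs
    constraint: ConstraintConfig = field(default_factory=ConstraintConfig)
    flank_bp: int = 100_000
    rate_cutoff: float = 2.0
    count_cutoff: int = 5
    top_fraction: float = 0.005
    age_rule: AgeGroupRule = field(default_factory=AgeGroupRule)
    sig_min_sample_share: float = 0.05
    sig_min_cohort_fraction: float = 0.10
    gene_sets_path: Path | None = None

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.inputs_dir is not None:
            self.inputs_dir = Path(self.inputs_dir)

    @property
    def resolved_inputs_dir(self) -> Path:
        return self.inputs_dir if self.inputs_dir is not None else self.out_dir / "inputs"

    # -- serialisation -------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        if sim is not None:
            cohorts = []
            for c in sim.pop("cohorts", []):
                c = dict(c)
                drivers = tuple(PlantedDriver(**pd_) for pd_ in c.pop("planted_drivers", []))
                age = AgeModel(**c.pop("age_model", {}))
                cohorts.append(CohortSpec(planted_drivers=drivers, age_model=age, **c))
            if cohorts:
                sim["cohorts"] = tuple(cohorts)
            for key in ("gene_span_bp_range", "exons_per_gene_range",
                        "background_score", "constrained_score"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(**sim)
        constraint = ConstraintConfig(**d.pop("constraint", {}))
        age_rule = AgeGroupRule(**d.pop("age_rule", {}))
        return cls(simulation=sim, constraint=constraint, age_rule=age_rule, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def echo(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            return obj
        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}


# ---------------------------------------------------------------------
# Input bundle
# ---------------------------------------------------------------------


@dataclass
class InputBundle:
    reference: dict[str, str]
    chrom_table: ChromosomeTable
    genes: list
    track: object
    features: dict
    metadata: pd.DataFrame
    variants: list[SomaticVariant]
    signatures: pd.DataFrame | None
    paths: dict


def _require(path: Path, what: str) -> Path:
    if not Path(path).exists():
        raise PipelineError(f"missing input: {what} at {path}")
    return Path(path)


def load_inputs(cfg: PipelineConfig) -> InputBundle:
    d = cfg.resolved_inputs_dir
    ref_path = _require(d / "reference.fa", "reference FASTA")
    genes_path = _require(d / "genes.bed", "gene models")
    track_path = _require(d / "constraint.bedgraph", "constraint track")
    meta_path = _require(d / "metadata.tsv", "sample metadata")
    vcf_dir = _require(d / "vcf", "VCF directory")
    reference = read_fasta(ref_path)
    chrom_table = ChromosomeTable.from_sequences(reference)
    cds_bed = d / "genes_cds.bed"
    genes = read_gene_models(genes_path, cds_bed if cds_bed.exists() else None)
    track = read_constraint_track(track_path, chrom_table)
    feature_paths = sorted(p for p in d.glob("*.bed") if p.name not in
                           ("genes.bed", "genes_cds.bed"))
    features = read_feature_tracks(feature_paths)
    metadata = read_sample_metadata(meta_path)
    vcfs = sorted(vcf_dir.glob("*.vcf"))
    variants = read_vcf_cohort(vcfs, metadata)
    sig_path = d / "signatures.tsv"
    signatures = read_signature_assignments(sig_path) if sig_path.exists() else None
    paths = {"reference": ref_path, "genes": genes_path, "track": track_path,
             "metadata": meta_path, "vcfs": vcfs}
    return InputBundle(reference, chrom_table, genes, track, features,
                       metadata, variants, signatures, paths)


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _jsonsafe(obj):
    """NaN -> null so summaries stay strict JSON."""
    if isinstance(obj, float):
        return obj if math.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _jsonsafe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonsafe(v) for v in obj]
    return obj


# ---------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig) -> dict:
    if cfg.simulation is None:
        raise PipelineError("simulate stage requested without a simulation config")
    sim = cfg.simulation
    if sim.seed != cfg.seed:
        sim = dataclasses.replace(sim, seed=cfg.seed)
    logger.info("[simulate] generating synthetic study (seed=%d)", cfg.seed)
    study = simulate_study(sim)
    write_simulation(study, cfg.resolved_inputs_dir)
    logger.info("[simulate] %d samples, %d variants, cutoff=%.4g",
                len(study.metadata), len(study.variants), study.cutoff)
    return {"n_samples": int(len(study.metadata)),
            "n_variants": int(len(study.variants)),
            "calibrated_cutoff": study.cutoff,
            "realized_constrained_fraction": study.realized_constrained_fraction}


_ANNOT_COLS = ["sample_id", "chrom", "pos", "ref", "alt", "var_type",
               "functional_class", "score", "is_nccm", "gene_assignments"]


def stage_annotate(cfg: PipelineConfig) -> dict:
    inputs = load_inputs(cfg)
    logger.info("[annotate] %d variants from %d samples",
                len(inputs.variants), len(inputs.metadata))
    all_cds = union_cds(inputs.genes)
    targets = build_all_targets(inputs.genes, cfg.flank_bp, inputs.chrom_table)
    index = build_target_index(targets)
    cutoff = cfg.constraint.resolve_cutoff(inputs.track)
    annotated = annotate_variants(inputs.variants, all_cds, index,
                                  inputs.chrom_table, inputs.track,
                                  cfg.constraint.indel_policy)
    annotated = call_nccms(annotated, cutoff)
    rows = [dict(sample_id=av.sample_id, chrom=av.chrom, pos=av.pos,
                 ref=av.variant.ref, alt=av.variant.alt, var_type=av.var_type,
                 functional_class=av.functional_class,
                 score=av.score, is_nccm=av.is_nccm,
                 gene_assignments=",".join(av.gene_assignments))
            for av in annotated]
    df = pd.DataFrame(rows, columns=_ANNOT_COLS)
    df = df.sort_values(["sample_id", "chrom", "pos", "ref", "alt"],
                        kind="mergesort").reset_index(drop=True)
    out = cfg.out_dir / "annotate"
    out.mkdir(parents=True, exist_ok=True)
    write_tsv(df, out / "annotated_variants.tsv")
    n_nccm = int(df["is_nccm"].sum())
    summary = {"cutoff": float(cutoff), "n_variants": int(len(df)),
               "n_nccms": n_nccm,
               "n_coding": int((df["functional_class"] == "coding").sum())}
    (out / "annotate_summary.json").write_text(
        json.dumps(_jsonsafe(summary), indent=2, sort_keys=True) + "\n")
    logger.info("[annotate] cutoff=%.4g, %d NCCMs called", cutoff, n_nccm)
    return summary


def _load_annotated(cfg: PipelineConfig) -> list[AnnotatedVariant]:
    path = _require(cfg.out_dir / "annotate" / "annotated_variants.tsv",
                    "annotated variants (run the annotate stage first)")
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str,
                                            "ref": str, "alt": str,
                                            "gene_assignments": str})
    out = []
    for row in df.itertuples(index=False):
        v = SomaticVariant(row.sample_id, row.chrom, int(row.pos), row.ref, row.alt)
        genes = tuple(row.gene_assignments.split(",")) \
            if isinstance(row.gene_assignments, str) and row.gene_assignments else ()
        out.append(AnnotatedVariant(v, float(row.score), row.functional_class,
                                    genes, bool(row.is_nccm)))
    return out


def stage_burden(cfg: PipelineConfig) -> dict:
    inputs = load_inputs(cfg)
    annotated = _load_annotated(cfg)
    targets = build_all_targets(inputs.genes, cfg.flank_bp, inputs.chrom_table)
    out = cfg.out_dir / "burden"
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    for cohort in sorted(inputs.metadata["cohort"].unique()):
        samples = set(inputs.metadata.loc[inputs.metadata["cohort"] == cohort,
                                          "sample_id"])
        subset = [av for av in annotated if av.sample_id in samples]
        nccms = nccms_only(subset)
        bt = burden_mod.compute_gene_burden(nccms, targets, len(samples), inputs.genes)
        cands = burden_mod.select_candidates(bt, cfg.rate_cutoff, cfg.count_cutoff)
        loci = burden_mod.locus_groups(nccms, [g.gene_id for g in inputs.genes])
        table = burden_mod.finalize_burden_table(bt, cands, loci)
        write_tsv(table, out / f"burden_{cohort}.tsv")
        dist, dist_summary = burden_mod.per_sample_distribution(bt, cands.rate_set)
        write_tsv(dist, out / f"per_sample_{cohort}.tsv")
        cand_df = table[table["in_rate_set"] | table["in_count_set"]]
        write_tsv(cand_df, out / f"candidates_{cohort}.tsv")
        summary[cohort] = {
            "n_samples": len(samples), "n_nccms": len(nccms),
            "rate_set": len(cands.rate_set), "count_set": len(cands.count_set),
            "union_set": len(cands.union_set), **dist_summary,
        }
        logger.info("[burden] %s: %d NCCMs, %d rate-set / %d count-set candidates",
                    cohort, len(nccms), len(cands.rate_set), len(cands.count_set))
    (out / "burden_summary.json").write_text(
        json.dumps(_jsonsafe(summary), indent=2, sort_keys=True) + "\n")
    return summary


def _burden_for(cfg, inputs, annotated, targets, cohort):
    samples = set(inputs.metadata.loc[inputs.metadata["cohort"] == cohort, "sample_id"])
    subset = [av for av in annotated if av.sample_id in samples]
    nccms = nccms_only(subset)
    bt = burden_mod.compute_gene_burden(nccms, targets, len(samples), inputs.genes)
    return subset, nccms, bt


def stage_stats(cfg: PipelineConfig) -> dict:
    inputs = load_inputs(cfg)
    annotated = _load_annotated(cfg)
    targets = build_all_targets(inputs.genes, cfg.flank_bp, inputs.chrom_table)
    gene_spans = {g.gene_id: g.span_bp for g in inputs.genes}
    cohorts = sorted(inputs.metadata["cohort"].unique())
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {}

    per_cohort = {c: _burden_for(cfg, inputs, annotated, targets, c) for c in cohorts}

    if len(cohorts) >= 2:
        a, b = cohorts[0], cohorts[1]
        cmp_ = cohort_stats.compare_cohort_rates(
            per_cohort[a][2].table, per_cohort[b][2].table, a, b, cfg.top_fraction)
        tables["cohort_comparison"] = pd.DataFrame([dataclasses.asdict(cmp_)])
        summary["cohort_comparison"] = {"direction": cmp_.direction,
                                        "p_all": cmp_.p_all, "p_top": cmp_.p_top}
        logger.info("[stats] cohort comparison %s vs %s: p_all=%.3g", a, b, cmp_.p_all)

    conf_rows = []
    repeats = inputs.features.get("repeats", {})
    for c in cohorts:
        subset, nccms, bt = per_cohort[c]
        cands = burden_mod.select_candidates(bt, cfg.rate_cutoff, cfg.count_cutoff)
        rep = cohort_stats.correlate_confounders(
            bt.table, subset, targets, gene_spans, inputs.reference,
            repeats, inputs.chrom_table.total_bp,
            cands.rate_set or tuple(
                bt.table.sort_values("rate_per_100kbp", ascending=False)
                .head(10)["gene_id"]),
            nccms)
        conf_rows.append(dict(cohort=c, **dataclasses.asdict(rep)))
    tables["confounders"] = pd.DataFrame(conf_rows)

    if inputs.signatures is not None and len(inputs.signatures):
        shift_rows = []
        filt_rows = []
        for c in cohorts:
            samples = set(inputs.metadata.loc[inputs.metadata["cohort"] == c,
                                              "sample_id"])
            sub = inputs.signatures[inputs.signatures["sample_id"].isin(samples)]
            if len(sub) == 0:
                continue
            retained = cohort_stats.filter_signatures(
                sub, n_samples=len(samples),
                min_sample_share=cfg.sig_min_sample_share,
                min_cohort_fraction=cfg.sig_min_cohort_fraction)
            filt_rows.append(dict(cohort=c, retained=",".join(retained)))
            classes = set(sub["mutation_class"])
            if {"coding", "nccm"} <= classes:
                for sig in retained:
                    res = cohort_stats.signature_shift_test(sub, sig, "coding", "nccm")
                    shift_rows.append(dict(
                        cohort=c, signature=sig,
                        coding_with=res.table[0][0], coding_without=res.table[0][1],
                        nccm_with=res.table[1][0], nccm_without=res.table[1][1],
                        odds_ratio=res.odds_ratio, p_value=res.p_value,
                        share_coding=res.share_a, share_nccm=res.share_b,
                        direction=res.direction))
        tables["signature_filter"] = pd.DataFrame(filt_rows)
        tables["signature_shift"] = pd.DataFrame(shift_rows)
        summary["signature_shift"] = {
            r["signature"] + "@" + r["cohort"]: r["p_value"] for r in shift_rows}

    overlap_rows = []
    for c in cohorts:
        _, nccms, _ = per_cohort[c]
        ov = cohort_stats.regulatory_overlap(nccms, inputs.features)
        ov.insert(0, "cohort", c)
        overlap_rows.append(ov)
    if overlap_rows:
        tables["regulatory_overlap"] = pd.concat(overlap_rows, ignore_index=True)

    out = cfg.out_dir / "stats"
    write_results(tables, out)
    return summary


def stage_subgroups(cfg: PipelineConfig) -> dict:
    inputs = load_inputs(cfg)
    annotated = _load_annotated(cfg)
    targets = build_all_targets(inputs.genes, cfg.flank_bp, inputs.chrom_table)
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {}
    # the subgroup analysis applies to the cohort(s) that carry subgroup labels
    has_subgroups = inputs.metadata.loc[inputs.metadata["subgroup"] != "NA", "cohort"]
    cohorts = sorted(has_subgroups.unique()) or sorted(inputs.metadata["cohort"].unique())
    cohort = cohorts[0]
    meta = inputs.metadata[inputs.metadata["cohort"] == cohort]
    samples = set(meta["sample_id"])
    nccms = nccms_only([av for av in annotated if av.sample_id in samples])
    bt = burden_mod.compute_gene_burden(nccms, targets, len(samples), inputs.genes)
    cands = burden_mod.select_candidates(bt, cfg.rate_cutoff, cfg.count_cutoff)
    candidate_genes = list(cands.rate_set)
    if len(candidate_genes) < 2:  # fall back to the top genes by rate
        candidate_genes = list(
            bt.table.sort_values(["rate_per_100kbp", "gene_id"],
                                 ascending=[False, True])
            .head(20)["gene_id"])
    rates = subgroup_analysis.stratified_rates(
        nccms, meta, targets, candidate_genes, cfg.age_rule)
    tables["stratified_rates"] = rates.to_frame()
    try:
        tau, pv = subgroup_analysis.kendall_matrix(rates)
        tables["kendall_tau"] = tau.reset_index(names="stratum")
        tables["kendall_p"] = pv.reset_index(names="stratum")
        summary["kendall"] = {f"{a}|{b}": float(tau.loc[a, b])
                              for i, a in enumerate(tau.index)
                              for b in tau.columns[i + 1:]}
    except ValueError as exc:
        logger.warning("[subgroups] kendall matrix skipped: %s", exc)
    pair = subgroup_analysis.age_pair_correlations(rates)
    tables["age_pair_correlation"] = pd.DataFrame([pair])
    loci = burden_mod.locus_groups(nccms, [g.gene_id for g in inputs.genes])
    cov = subgroup_analysis.patient_coverage(nccms, meta, candidate_genes,
                                             loci, cfg.age_rule)
    tables["patient_coverage"] = cov
    summary["patient_coverage"] = {
        r["stratum"]: r["frac_with_nccm"] for _, r in cov.iterrows()}

    gene_sets = {}
    if cfg.gene_sets_path is not None:
        gene_sets = subgroup_analysis.read_gene_sets(cfg.gene_sets_path)
    else:
        truth_path = cfg.resolved_inputs_dir / "truth.json"
        if truth_path.exists():
            truth = read_truth(truth_path)
            planted = sorted({d.gene_id for ds in truth.planted_drivers.values()
                              for d in ds})
            if planted:
                gene_sets = {"planted_drivers": planted}
    tally_rows = []
    known = [g.gene_id for g in inputs.genes]
    for name, members in sorted(gene_sets.items()):
        tally = subgroup_analysis.geneset_tally(nccms, members, meta, known,
                                                cfg.age_rule, name)
        per = tally.per_stratum.copy()
        per.insert(0, "set_name", name)
        per.insert(1, "total_nccms", tally.total_nccms)
        per.insert(2, "genes_hit", tally.genes_hit)
        tally_rows.append(per)
    if tally_rows:
        tables["geneset_tally"] = pd.concat(tally_rows, ignore_index=True)

    write_results(tables, cfg.out_dir / "subgroups")
    summary["cohort"] = cohort
    summary["n_candidates"] = len(candidate_genes)
    logger.info("[subgroups] cohort %s, %d candidate genes", cohort, len(candidate_genes))
    return summary


def run_pipeline(cfg: PipelineConfig, stages: Sequence[str] = STAGES) -> dict:
    """Run the requested stages in order and write the machine-readable
    run summary. Raises on the first stage error."""
    for s in stages:
        if s not in STAGES:
            raise PipelineError(f"unknown stage {s!r}")
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    funcs = {"simulate": stage_simulate, "annotate": stage_annotate,
             "burden": stage_burden, "stats": stage_stats,
             "subgroups": stage_subgroups}
    if "simulate" not in stages and cfg.simulation is None:
        load_inputs(cfg)  # fail early with a named-file error
    summary: dict = {"config": cfg.echo(), "seed": cfg.seed, "stages": {}}
    for s in STAGES:
        if s not in stages:
            continue
        logger.info("[%s] start", s)
        summary["stages"][s] = funcs[s](cfg)
    d = cfg.resolved_inputs_dir
    if d.exists():
        summary["input_digests"] = {
            p.name: _digest(p) for p in sorted(d.glob("*")) if p.is_file()}
    (cfg.out_dir / "run_summary.json").write_text(
        json.dumps(_jsonsafe(summary), indent=2, sort_keys=True) + "\n")
    return summary
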