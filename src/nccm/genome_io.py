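"""Readers and writers for the standard formats the pipeline touches.

Every ingested feature is converted to the internal convention (0-based
half-open) at this boundary, whatever the source dialect: VCF and GFF3
are 1-based, BED and bedGraph already half-open. Writers are
deterministic -- stable column order, fixed float precision -- so a
rerun on identical inputs is byte-identical.
"""

from __future__ import annotations

import json
import re
from collections.abc import Mapping as AbcMapping
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constraint import ConstraintTrack
from .region_model import GeneModel, IntervalSet, RegionError

VAR_SNV = "SNV"
VAR_MNV = "MNV"
VAR_INS = "INS"
VAR_DEL = "DEL"

#: float format used by every TSV writer
FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------
# Core records
# ---------------------------------------------------------------------


class ChromosomeTable(AbcMapping):
    """Ordered chromosome name -> length mapping."""

    def __init__(self, lengths: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(lengths.items()) if isinstance(lengths, Mapping) else list(lengths)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise FormatError("duplicate chromosome names")
        for n, ln in items:
            if int(ln) <= 0:
                raise FormatError(f"chromosome {n!r} has non-positive length")
        self._lengths = {n: int(ln) for n, ln in items}

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __iter__(self):
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._lengths)

    @property
    def total_bp(self) -> int:
        return sum(self._lengths.values())

    @classmethod
    def from_sequences(cls, seqs: Mapping[str, str]) -> "ChromosomeTable":
        return cls({c: len(s) for c, s in seqs.items()})


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic call, one ALT allele. ``pos`` is the 1-based position
    of the first REF base (VCF convention)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise FormatError("REF and ALT must be non-empty")

    @property
    def var_type(self) -> str:
        lr, la = len(self.ref), len(self.alt)
        if lr == la:
            return VAR_SNV if lr == 1 else VAR_MNV
        return VAR_DEL if lr > la else VAR_INS

    @property
    def start0(self) -> int:
        return self.pos - 1

    @property
    def affected_span(self) -> tuple[int, int]:
        """0-based half-open span of affected reference bases.

        SNV/MNV: the substituted bases. DEL: the deleted bases (the
        anchor base is shared and unaffected). INS: the anchor base.
        """
        t = self.var_type
        if t == VAR_DEL:
            return self.start0 + 1, self.start0 + len(self.ref)
        if t == VAR_INS:
            return self.start0, self.start0 + 1
        return self.start0, self.start0 + len(self.ref)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    cohort: str
    subgroup: str
    age_years: float

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise FormatError(f"sample {self.sample_id}: negative age")


# ---------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------

_SAMPLE_META_RE = re.compile(r"##SAMPLE=<ID=([^,>]+)")


def _vcf_sample_id(path, header_text: str) -> str:
    m = _SAMPLE_META_RE.search(header_text)
    if m:
        return m.group(1)
    return Path(path).stem.removesuffix(".vcf")


def read_vcf_cohort(
    paths: Sequence, metadata: pd.DataFrame | Sequence[SampleMeta]
) -> list[SomaticVariant]:
    """Read per-sample VCFs; one record per ALT allele (multi-allelic
    sites are split). The sample id comes from a ##SAMPLE header line,
    falling back to the file stem, and must exist in the metadata."""
    if isinstance(metadata, pd.DataFrame):
        known = set(metadata["sample_id"])
    else:
        known = {m.sample_id for m in metadata}
    out: list[SomaticVariant] = []
    for path in sorted(str(p) for p in paths):
        with pysam.VariantFile(path) as vf:
            sample = _vcf_sample_id(path, str(vf.header))
            if sample not in known:
                raise FormatError(f"{path}: sample {sample!r} not in metadata")
            for i, rec in enumerate(vf, start=1):
                try:
                    if rec.alts is None:
                        continue
                    for alt in rec.alts:
                        if alt is None or alt.startswith("<") or alt == "*":
                            raise FormatError(f"unsupported ALT {alt!r}")
                        out.append(
                            SomaticVariant(sample, rec.chrom, rec.pos, rec.ref, alt)
                        )
                except FormatError:
                    raise
                except Exception as exc:  # malformed record
                    raise FormatError(f"{path}: record {i}: {exc}") from exc
    return out


def write_vcf(path, sample_id: str, variants: Sequence[SomaticVariant],
              chrom_table: ChromosomeTable) -> None:
    """Write one sample's calls as minimal VCF v4.2 (CHROM/POS/REF/ALT,
    sample identity in the header metadata)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##SAMPLE=<ID={sample_id}>\n")
        for name in chrom_table.names:
            fh.write(f"##contig=<ID={name},length={chrom_table[name]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------
# Gene models (BED12 [+ CDS companion] or GFF3 subset)
# ---------------------------------------------------------------------

_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
]


def _read_bed12(path, cds_path=None) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, names=_BED12_COLS,
                     dtype={"chrom": str, "name": str}, comment="#")
    companion: dict[str, list[tuple[int, int]]] = {}
    comp_chrom: dict[str, str] = {}
    if cds_path is not None:
        cdf = pd.read_csv(cds_path, sep="\t", header=None, comment="#",
                          usecols=[0, 1, 2, 3],
                          names=["chrom", "start", "end", "name"],
                          dtype={"chrom": str, "name": str})
        for row in cdf.itertuples(index=False):
            companion.setdefault(row.name, []).append((int(row.start), int(row.end)))
            comp_chrom[row.name] = row.chrom
    genes = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        if len(sizes) != int(row.block_count) or len(offsets) != int(row.block_count):
            raise FormatError(f"{path}: gene {row.name}: inconsistent block fields")
        exon_pairs = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
        exons = IntervalSet.from_pairs(row.chrom, exon_pairs)
        if row.name in companion:
            if comp_chrom[row.name] != row.chrom:
                raise FormatError(f"CDS companion for {row.name} on wrong chromosome")
            cds = IntervalSet.from_pairs(row.chrom, companion[row.name])
        else:
            thick = int(row.thick_start), int(row.thick_end)
            if thick[0] >= thick[1]:
                cds = IntervalSet.empty(row.chrom)
            else:
                cds = exons.clip(*thick)
        try:
            genes.append(GeneModel(
                gene_id=row.name, chrom=row.chrom, tx_start=start, tx_end=end,
                exons=exons, cds=cds, symbol=row.name,
                strand=row.strand if row.strand in "+-" else "+",
            ))
        except RegionError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return genes


_GFF_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


def _read_gff3(path) -> list[GeneModel]:
    """GFF3 subset: gene / mRNA (or transcript) / exon / CDS, 1-based
    closed intervals converted to internal half-open."""
    gene_rows: dict[str, dict] = {}
    parent_of: dict[str, str] = {}
    exon_pairs: dict[str, list[tuple[int, int]]] = {}
    cds_pairs: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: bad GFF line: {line.strip()!r}")
            chrom, _, ftype, start, end, _, strand, _, attr_s = fields
            attrs = dict(_GFF_ATTR_RE.findall(attr_s))
            s0, e0 = int(start) - 1, int(end)  # 1-based closed -> half-open
            if ftype == "gene":
                gid = attrs["ID"]
                gene_rows[gid] = dict(chrom=chrom, start=s0, end=e0, strand=strand,
                                      symbol=attrs.get("Name", gid))
            elif ftype in ("mRNA", "transcript"):
                parent_of[attrs["ID"]] = attrs["Parent"]
            elif ftype in ("exon", "CDS"):
                parent = attrs["Parent"].split(",")[0]
                gid = parent_of.get(parent, parent)
                (exon_pairs if ftype == "exon" else cds_pairs).setdefault(gid, []).append((s0, e0))
    genes = []
    for gid, row in gene_rows.items():
        exons = IntervalSet.from_pairs(row["chrom"], exon_pairs.get(gid, [(row["start"], row["end"])]))
        cds = IntervalSet.from_pairs(row["chrom"], cds_pairs.get(gid, []))
        if not cds.subtract(exons).is_empty:
            raise FormatError(f"{path}: CDS outside exons for gene {gid}")
        genes.append(GeneModel(gene_id=gid, chrom=row["chrom"], tx_start=row["start"],
                               tx_end=row["end"], exons=exons, cds=cds,
                               symbol=row["symbol"], strand=row["strand"] if row["strand"] in "+-" else "+"))
    return genes


def read_gene_models(path, cds_path=None) -> list[GeneModel]:
    """Read gene models from BED12 (optionally with a companion CDS BED,
    which overrides the thickStart/thickEnd CDS) or a GFF3 subset.
    Output is sorted by (chrom, tx_start, gene_id)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        genes = _read_gff3(path)
    else:
        genes = _read_bed12(path, cds_path)
    return sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.gene_id))


def write_gene_models_bed12(path, genes: Sequence[GeneModel], cds_path=None) -> None:
    """Write BED12 with thickStart/thickEnd spanning the CDS; optionally
    also a companion CDS BED with one line per CDS interval."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.gene_id)):
            sizes = ",".join(str(e - s) for s, e in g.exons.pairs())
            offsets = ",".join(str(s - g.tx_start) for s, _ in g.exons.pairs())
            if g.cds.is_empty:
                thick_s = thick_e = g.tx_start
            else:
                thick_s = int(g.cds.starts[0])
                thick_e = int(g.cds.ends[-1])
            fh.write("\t".join(map(str, [
                g.chrom, g.tx_start, g.tx_end, g.gene_id, 0, g.strand,
                thick_s, thick_e, "0", len(g.exons), sizes, offsets,
            ])) + "\n")
    if cds_path is not None:
        with open(cds_path, "w") as fh:
            for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.gene_id)):
                for s, e in g.cds.pairs():
                    fh.write(f"{g.chrom}\t{s}\t{e}\t{g.gene_id}\n")


# ---------------------------------------------------------------------
# Constraint track (bedGraph, fixedStep wiggle)
# ---------------------------------------------------------------------


def read_constraint_track(path, chrom_table: ChromosomeTable) -> ConstraintTrack:
    """bedGraph (0-based half-open) or fixedStep wiggle into a dense
    track. Unscored positions stay NaN -- distinguishable from 0."""

    def records():
        with open(path) as fh:
            chrom, pos, step, span = None, 0, 1, 1
            mode = "bedgraph"
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                if line.startswith("fixedStep"):
                    kv = dict(f.split("=") for f in line.split()[1:])
                    chrom = kv["chrom"]
                    pos = int(kv["start"]) - 1  # wiggle is 1-based
                    step = int(kv.get("step", 1))
                    span = int(kv.get("span", 1))
                    mode = "wig"
                    continue
                if mode == "wig":
                    yield chrom, pos, pos + span, float(line)
                    pos += step
                else:
                    fields = line.split()
                    if len(fields) != 4:
                        raise FormatError(f"{path}: bad bedGraph line {line!r}")
                    yield fields[0], int(fields[1]), int(fields[2]), float(fields[3])

    return ConstraintTrack.from_records(chrom_table, records())


def write_bedgraph(path, track: ConstraintTrack) -> None:
    """Dense track to bedGraph, collapsing runs of identical adjacent
    scores; NaN (unscored) positions are omitted. %.9g round-trips
    float32 exactly."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            arr = track.array(chrom)
            if arr.size == 0:
                continue
            scored = ~np.isnan(arr)
            # run boundaries: score change or scored-mask change
            change = np.empty(arr.size, dtype=bool)
            change[0] = True
            same = (arr[1:] == arr[:-1]) | (np.isnan(arr[1:]) & np.isnan(arr[:-1]))
            change[1:] = ~same
            starts = np.flatnonzero(change)
            ends = np.append(starts[1:], arr.size)
            for s, e in zip(starts, ends):
                if scored[s]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{float(arr[s]):.9g}\n")


# ---------------------------------------------------------------------
# Feature tracks (BED) and metadata / signature tables
# ---------------------------------------------------------------------


def read_feature_tracks(paths: Sequence) -> dict[str, dict[str, IntervalSet]]:
    """Each BED file becomes one named (file stem), merged per-chromosome
    IntervalSet collection."""
    out: dict[str, dict[str, IntervalSet]] = {}
    for path in paths:
        name = Path(path).stem
        pairs: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                pairs.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
        out[name] = {c: IntervalSet.from_pairs(c, p) for c, p in sorted(pairs.items())}
    return out


def write_feature_track(path, sets_by_chrom: Mapping[str, IntervalSet]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sets_by_chrom):
            for s, e in sets_by_chrom[chrom].pairs():
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_sample_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cohort": str, "subgroup": str})
    required = {"sample_id", "cohort", "subgroup", "age_years"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    if (df["age_years"] < 0).any():
        raise FormatError(f"{path}: negative age_years")
    return df


def read_signature_assignments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str,
                                            "mutation_class": str, "signature": str})
    required = {"sample_id", "chrom", "pos", "mutation_class", "signature"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing signature columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def write_results(tables: Mapping[str, pd.DataFrame], out_dir,
                  summary: Mapping | None = None) -> list[Path]:
    """One TSV per analysis table plus an optional JSON run summary.
    Stable column order and fixed float precision make reruns
    byte-identical."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        write_tsv(df, path)
        written.append(path)
    if summary is not None:
        path = out_dir / "run_summary.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written.append(path)
    return written
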