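import numpy as np
import pandas as pd
import pytest

from nccm.constraint import ConstraintTrack, TrackError
from nccm.genome_io import (
    ChromosomeTable,
    FormatError,
    SomaticVariant,
    read_constraint_track,
    read_feature_tracks,
    read_gene_models,
    read_vcf_cohort,
    write_bedgraph,
    write_gene_models_bed12,
    write_results,
    write_vcf,
)
from nccm.region_model import IntervalSet, GeneModel


class TestSomaticVariant:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("A", "T", "SNV"),
        ("AT", "GC", "MNV"),
        ("AT", "A", "DEL"),
        ("A", "AT", "INS"),
    ])
    def test_var_type_from_lengths(self, ref, alt, expected):
        assert SomaticVariant("s", "chr1", 10, ref, alt).var_type == expected

    def test_deletion_affected_span_skips_anchor(self):
        # VCF anchoring: ref=AT alt=A at pos 10 deletes the base at pos 11
        v = SomaticVariant("s", "chr1", 10, "AT", "A")
        assert v.affected_span == (10, 11)  # 0-based half-open

    def test_insertion_anchored_at_base(self):
        v = SomaticVariant("s", "chr1", 10, "A", "ATT")
        assert v.affected_span == (9, 10)

    def test_validation(self):
        with pytest.raises(FormatError):
            SomaticVariant("s", "chr1", 0, "A", "T")
        with pytest.raises(FormatError):
            SomaticVariant("s", "chr1", 1, "", "T")


class TestChromosomeTable:
    def test_mapping_protocol(self):
        t = ChromosomeTable({"chr1": 100, "chr2": 50})
        assert t["chr1"] == 100 and "chr2" in t and t.total_bp == 150

    def test_duplicate_names_rejected(self):
        with pytest.raises(FormatError):
            ChromosomeTable([("chr1", 10), ("chr1", 20)])


class TestVcfRoundTrip:
    def make_meta(self, *samples):
        return pd.DataFrame({"sample_id": samples, "cohort": "MB",
                             "subgroup": "NA", "age_years": 5.0})

    def test_write_then_read_identical(self, tmp_path):
        table = ChromosomeTable({"chr1": 1000, "chr2": 500})
        variants = [
            SomaticVariant("s1", "chr1", 5, "A", "T"),
            SomaticVariant("s1", "chr1", 10, "AT", "A"),
            SomaticVariant("s1", "chr2", 7, "G", "GCC"),
        ]
        path = tmp_path / "s1.vcf"
        write_vcf(path, "s1", variants, table)
        back = read_vcf_cohort([path], self.make_meta("s1"))
        assert back == sorted(variants, key=lambda v: (v.chrom, v.pos))

    def test_multiallelic_split(self, tmp_path):
        path = tmp_path / "s1.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##SAMPLE=<ID=s1>\n"
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t5\t.\tA\tT,G\t.\t.\t.\n")
        back = read_vcf_cohort([path], self.make_meta("s1"))
        assert [(v.ref, v.alt) for v in back] == [("A", "T"), ("A", "G")]

    def test_empty_vcf_is_not_an_error(self, tmp_path):
        path = tmp_path / "s1.vcf"
        write_vcf(path, "s1", [], ChromosomeTable({"chr1": 100}))
        assert read_vcf_cohort([path], self.make_meta("s1")) == []

    def test_unknown_sample_rejected(self, tmp_path):
        path = tmp_path / "sX.vcf"
        write_vcf(path, "sX", [], ChromosomeTable({"chr1": 100}))
        with pytest.raises(FormatError, match="sX"):
            read_vcf_cohort([path], self.make_meta("s1"))


class TestGeneModels:
    def _gene(self):
        exons = IntervalSet.from_pairs("chr1", [(100, 200), (300, 400), (500, 650)])
        cds = exons.clip(150, 600)
        return GeneModel("gA", "chr1", 100, 650, exons, cds, symbol="gA", strand="-")

    def test_bed12_round_trip(self, tmp_path):
        genes = [self._gene()]
        path = tmp_path / "genes.bed"
        write_gene_models_bed12(path, genes)
        back = read_gene_models(path)
        assert back == genes

    def test_bed12_blocks_reconstructed(self, tmp_path):
        path = tmp_path / "genes.bed"
        write_gene_models_bed12(path, [self._gene()])
        g = read_gene_models(path)[0]
        assert len(g.exons) == 3
        assert g.exons.pairs() == [(100, 200), (300, 400), (500, 650)]

    def test_companion_cds_overrides_thick(self, tmp_path):
        path = tmp_path / "genes.bed"
        cds_path = tmp_path / "cds.bed"
        write_gene_models_bed12(path, [self._gene()], cds_path)
        g = read_gene_models(path, cds_path)[0]
        assert g.cds.pairs() == [(150, 200), (300, 400), (500, 600)]

    def test_gff3_one_based_conversion(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1;Name=G1\n"
            "chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\texon\t101\t200\t.\t+\t.\tID=e1;Parent=t1\n"
            "chr1\tsrc\tCDS\t121\t180\t.\t+\t0\tID=c1;Parent=t1\n")
        g = read_gene_models(path)[0]
        assert (g.tx_start, g.tx_end) == (100, 200)
        assert g.cds.pairs() == [(120, 180)]

    def test_cds_outside_exons_names_gene(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(
            "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=gBad\n"
            "chr1\tsrc\texon\t101\t150\t.\t+\t.\tID=e;Parent=gBad\n"
            "chr1\tsrc\tCDS\t151\t190\t.\t+\t0\tID=c;Parent=gBad\n")
        with pytest.raises(FormatError, match="gBad"):
            read_gene_models(path)

    def test_unsorted_input_sorted_output(self, tmp_path):
        g1 = GeneModel("b", "chr1", 500, 700,
                       IntervalSet.from_pairs("chr1", [(500, 700)]),
                       IntervalSet.empty("chr1"))
        g2 = GeneModel("a", "chr1", 100, 300,
                       IntervalSet.from_pairs("chr1", [(100, 300)]),
                       IntervalSet.empty("chr1"))
        path = tmp_path / "genes.bed"
        write_gene_models_bed12(path, [g1, g2])
        assert [g.gene_id for g in read_gene_models(path)] == ["a", "b"]


class TestConstraintTrackIO:
    def test_bedgraph_semantics(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        path.write_text("chr1\t10\t13\t1.5\n")
        track = read_constraint_track(path, ChromosomeTable({"chr1": 20}))
        assert [track.score_at("chr1", p) for p in (10, 11, 12)] == [1.5] * 3
        assert np.isnan(track.score_at("chr1", 13))  # missing, not 0

    def test_overlap_rejected(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        path.write_text("chr1\t0\t10\t1.0\nchr1\t5\t8\t2.0\n")
        with pytest.raises(TrackError):
            read_constraint_track(path, ChromosomeTable({"chr1": 20}))

    def test_fixed_step_wiggle(self, tmp_path):
        path = tmp_path / "t.wig"
        path.write_text("fixedStep chrom=chr1 start=11 step=1\n0.5\n0.75\n")
        track = read_constraint_track(path, ChromosomeTable({"chr1": 20}))
        assert track.score_at("chr1", 10) == 0.5
        assert track.score_at("chr1", 11) == 0.75

    def test_round_trip(self, tmp_path, rng):
        scores = np.full(500, np.nan, dtype=np.float32)
        idx = rng.choice(500, size=200, replace=False)
        scores[idx] = rng.normal(0, 2, size=200).astype(np.float32).clip(-20, 9)
        track = ConstraintTrack({"chr1": scores})
        path = tmp_path / "t.bedgraph"
        write_bedgraph(path, track)
        back = read_constraint_track(path, ChromosomeTable({"chr1": 500}))
        np.testing.assert_array_equal(back.array("chr1"), scores)


class TestFeatureTracks:
    def test_merge_and_name(self, tmp_path):
        p = tmp_path / "repeats.bed"
        p.write_text("chr1\t0\t10\nchr1\t5\t20\nchr2\t3\t4\n")
        tracks = read_feature_tracks([p])
        assert set(tracks) == {"repeats"}
        assert tracks["repeats"]["chr1"].pairs() == [(0, 20)]

    def test_empty_file_empty_set(self, tmp_path):
        p = tmp_path / "dnase.bed"
        p.write_text("")
        assert read_feature_tracks([p])["dnase"] == {}


class TestWriteResults:
    def test_deterministic_rerun(self, tmp_path):
        df = pd.DataFrame({"gene_id": ["a", "b"], "rate": [1 / 3, 2 / 7]})
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        write_results({"burden": df}, d1, summary={"n": 2})
        write_results({"burden": df}, d2, summary={"n": 2})
        assert (d1 / "burden.tsv").read_bytes() == (d2 / "burden.tsv").read_bytes()
        assert (d1 / "run_summary.json").read_bytes() == \
            (d2 / "run_summary.json").read_bytes()

    def test_empty_table_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["gene_id", "rate"])
        write_results({"candidates": df}, tmp_path)
        assert (tmp_path / "candidates.tsv").read_text() == "gene_id\trate\n"
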