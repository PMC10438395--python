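import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nccm.region_model import (
    IntervalSet,
    GeneModel,
    RegionError,
    build_all_targets,
    build_target_index,
    build_target_region,
    classify_variant,
    gc_fraction,
    merge_intervals,
    subtract_intervals,
    union_cds,
)
from nccm.genome_io import SomaticVariant

from oracles import mask_to_pairs, target_mask


def iset(pairs, chrom="chr1"):
    return IntervalSet.from_pairs(chrom, pairs)


class TestIntervalAlgebra:
    @pytest.mark.parametrize("raw,expected", [
        ([(0, 10), (5, 20)], [(0, 20)]),          # overlap merge
        ([(0, 10), (10, 20)], [(0, 20)]),         # abutting merge
        ([], []),                                  # identity
        ([(5, 6), (0, 1), (2, 3)], [(0, 1), (2, 3), (5, 6)]),  # sorting
    ])
    def test_merge(self, raw, expected):
        assert merge_intervals("chr1", raw).pairs() == expected

    def test_merge_rejects_empty_interval(self):
        with pytest.raises(RegionError):
            merge_intervals("chr1", [(5, 5)])

    @pytest.mark.parametrize("a,b,expected", [
        ([(0, 100)], [(40, 60)], [(0, 40), (60, 100)]),  # split
        ([(0, 100)], [(0, 100)], []),                     # a minus a
        ([(0, 100)], [], [(0, 100)]),                     # subtract empty
    ])
    def test_subtract(self, a, b, expected):
        assert subtract_intervals(iset(a), iset(b)).pairs() == expected

    def test_subtract_chromosome_mismatch(self):
        with pytest.raises(RegionError):
            iset([(0, 5)]).subtract(iset([(0, 5)], chrom="chr2"))

    def test_total_length(self):
        s = iset([(0, 40), (60, 100)])
        assert s.total_length_bp == 80

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_algebra_matches_per_base_oracle(self, data):
        """subtract/intersect/merge on random interval sets equal a
        per-base membership scan on [0, 1000)."""
        def random_set(key):
            n = data.draw(st.integers(0, 8), label=f"n_{key}")
            pairs = []
            for i in range(n):
                s = data.draw(st.integers(0, 998), label=f"s_{key}{i}")
                e = data.draw(st.integers(s + 1, 1000), label=f"e_{key}{i}")
                pairs.append((s, e))
            return iset(pairs)

        def mask(s):
            m = np.zeros(1000, dtype=bool)
            for a, b in s.pairs():
                m[a:b] = True
            return m

        a, b = random_set("a"), random_set("b")
        assert mask_to_pairs(mask(a) & ~mask(b)) == a.subtract(b).pairs()
        assert mask_to_pairs(mask(a) & mask(b)) == a.intersect(b).pairs()
        assert mask_to_pairs(mask(a) | mask(b)) == a.union(b).pairs()
        # merged length never exceeds the sum of raw widths
        assert a.union(b).total_length_bp <= a.total_length_bp + b.total_length_bp

    def test_contains_vectorised(self):
        s = iset([(10, 20), (30, 40)])
        got = s.contains([9, 10, 19, 20, 35, 40])
        assert got.tolist() == [False, True, True, False, True, False]


class TestGeneModel:
    def test_cds_outside_exons_rejected(self):
        with pytest.raises(RegionError, match="CDS outside exons"):
            GeneModel("g", "chr1", 0, 1000, iset([(100, 200)]), iset([(150, 250)]))

    def test_exons_outside_span_rejected(self):
        with pytest.raises(RegionError):
            GeneModel("g", "chr1", 0, 100, iset([(50, 150)]), iset([]))


class TestTargetRegion:
    def test_worked_example(self):
        """Gene span [200000,210000) on a 1 Mb chromosome, own CDS
        [202000,205000), no neighbours, 100 kb flank -> two blocks of
        total length 207,000."""
        g = GeneModel("g", "chr1", 200_000, 210_000,
                      iset([(200_000, 210_000)]), iset([(202_000, 205_000)]))
        tr = build_target_region(g, union_cds([g]), 100_000, {"chr1": 1_000_000})
        assert tr.regions.pairs() == [(100_000, 202_000), (205_000, 310_000)]
        assert tr.length_bp == 207_000

    def test_left_edge_clipped_matches_oracle(self):
        g = GeneModel("g", "chr1", 50_000, 60_000,
                      iset([(50_000, 60_000)]), iset([(52_000, 55_000)]))
        tr = build_target_region(g, union_cds([g]), 100_000, {"chr1": 1_000_000})
        m = target_mask(g, [g], 100_000, 1_000_000)
        assert tr.regions.pairs() == mask_to_pairs(m)
        assert tr.length_bp == int(m.sum())

    def test_neighbour_cds_excluded(self, study):
        """No target region base ever overlaps any gene's CDS."""
        cds = union_cds(study.genes)
        targets = build_all_targets(study.genes, 20_000, study.chrom_table)
        for tr in targets.values():
            if tr.regions.is_empty:
                continue
            assert tr.regions.intersect(cds[tr.regions.chrom]).is_empty

    def test_negative_flank_rejected(self):
        g = GeneModel("g", "chr1", 100, 200, iset([(100, 200)]), iset([]))
        with pytest.raises(RegionError):
            build_target_region(g, {}, -1, {"chr1": 1000})


def _two_gene_setup():
    g1 = GeneModel("g1", "chr1", 100_000, 110_000,
                   iset([(100_000, 110_000)]), iset([(101_000, 104_000)]))
    g2 = GeneModel("g2", "chr1", 140_000, 150_000,
                   iset([(140_000, 150_000)]), iset([(141_000, 144_000)]))
    genes = [g1, g2]
    lengths = {"chr1": 1_000_000}
    cds = union_cds(genes)
    targets = build_all_targets(genes, 100_000, lengths)
    return genes, cds, build_target_index(targets), lengths


class TestClassifyVariant:
    def test_cds_position_is_coding(self):
        genes, cds, index, lengths = _two_gene_setup()
        v = SomaticVariant("s", "chr1", 102_001, "A", "T")
        cls, hit = classify_variant(v, cds, index, lengths)
        assert cls == "coding" and hit == ()

    def test_shared_locus_assigns_both_genes(self):
        genes, cds, index, lengths = _two_gene_setup()
        v = SomaticVariant("s", "chr1", 125_001, "A", "T")  # between the genes
        cls, hit = classify_variant(v, cds, index, lengths)
        assert cls == "noncoding_target" and hit == ("g1", "g2")

    def test_far_position_is_noncoding_other(self):
        genes, cds, index, lengths = _two_gene_setup()
        v = SomaticVariant("s", "chr1", 400_001, "A", "T")
        cls, hit = classify_variant(v, cds, index, lengths)
        assert cls == "noncoding_other" and hit == ()

    def test_deletion_touching_cds_is_coding(self):
        genes, cds, index, lengths = _two_gene_setup()
        # anchor base just before the CDS; first deleted base is CDS
        v = SomaticVariant("s", "chr1", 101_000, "AC", "A")
        cls, _ = classify_variant(v, cds, index, lengths)
        assert cls == "coding"

    def test_unknown_chromosome_rejected(self):
        genes, cds, index, lengths = _two_gene_setup()
        with pytest.raises(RegionError):
            classify_variant(SomaticVariant("s", "chrX", 5, "A", "T"),
                             cds, index, lengths)

    def test_exactly_one_class(self, study):
        """Classification is exhaustive and exclusive at the class level."""
        cds = union_cds(study.genes)
        targets = build_all_targets(study.genes, 20_000, study.chrom_table)
        index = build_target_index(targets)
        for v in study.variants[:400]:
            cls, hit = classify_variant(v, cds, index, study.chrom_table)
            assert cls in ("coding", "noncoding_target", "noncoding_other")
            assert (cls == "noncoding_target") == bool(hit)


class TestGcFraction:
    @pytest.mark.parametrize("seq,expected", [("GGCC", 1.0), ("ATAT", 0.0)])
    def test_pure_sequences(self, seq, expected):
        assert gc_fraction(iset([(0, 4)]), {"chr1": seq}) == expected

    def test_ambiguous_bases_excluded(self):
        assert gc_fraction(iset([(0, 4)]), {"chr1": "GNNA"}) == 0.5

    def test_empty_region_undefined(self):
        assert np.isnan(gc_fraction(IntervalSet.empty("chr1"), {"chr1": "ACGT"}))

    def test_matches_counting_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        s = iset([(1_000, 4_000), (6_000, 9_500)])
        sub = seq[1_000:4_000] + seq[6_000:9_500]
        expected = (sub.count("G") + sub.count("C")) / len(sub)
        assert gc_fraction(s, {"chr1": seq}) == pytest.approx(expected, abs=1e-12)
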