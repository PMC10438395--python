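import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nccm.cohort_stats import (
    compare_cohort_rates,
    correlate_confounders,
    filter_signatures,
    regulatory_overlap,
    signature_shift_test,
)
from nccm.constraint import AnnotatedVariant
from nccm.genome_io import SomaticVariant
from nccm.region_model import IntervalSet, TargetRegion
from nccm.synthetic_cohort import simulate_signature_assignments

from oracles import fisher_point_two_sided, pearson_naive


def burden_frame(rates):
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(len(rates))],
        "nccm_count": np.arange(len(rates)),
        "target_len_bp": 100_000,
        "rate_per_100kbp": rates,
        "rate_per_patient": rates,
    })


class TestCompareCohortRates:
    def test_identical_tables_no_difference(self):
        df = burden_frame([1.0, 2.0, 3.0, 4.0])
        res = compare_cohort_rates(df, df.copy(), "A", "B")
        assert res.t_all == pytest.approx(0.0)
        assert res.p_all == pytest.approx(1.0)

    def test_top_fraction_count(self):
        df = burden_frame(np.linspace(0, 5, 2000))
        res = compare_cohort_rates(df, df.copy(), top_fraction=0.005)
        assert res.top_n_a == res.top_n_b == 10

    def test_detects_configured_effect(self, rng):
        """A cohort with systematically higher per-patient rates is
        called at p < 0.05 with 500+ genes."""
        a = burden_frame(rng.gamma(2.0, 1.0, size=600) * 1.5)
        b = burden_frame(rng.gamma(2.0, 1.0, size=600))
        res = compare_cohort_rates(a, b, "MB", "PA")
        assert res.mean_a > res.mean_b
        assert res.p_all < 0.05
        assert res.direction == "MB > PA"

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            compare_cohort_rates(burden_frame([1.0]), burden_frame([1.0, 2.0]))


class TestConfounders:
    def _setup(self, rates, all_variants=(), nccms=(), repeats=None, seqs=None):
        n = len(rates)
        df = burden_frame(rates)
        targets = {f"g{i}": TargetRegion(
            f"g{i}", IntervalSet.from_pairs("chr1", [(i * 1000, (i + 1) * 1000)]),
            1000) for i in range(n)}
        df["target_len_bp"] = 1000
        spans = {f"g{i}": 500 for i in range(n)}
        repeats = repeats or {}
        return correlate_confounders(df, list(all_variants), targets, spans,
                                     seqs, repeats, 100_000,
                                     [f"g{i}" for i in range(n)], list(nccms))

    def test_perfect_gc_correlation(self):
        # sequence engineered so per-target GC is proportional to rate
        n = 4
        seq = []
        for i in range(n):
            gc = int(1000 * (i + 1) / (n + 1))
            seq.append("G" * gc + "A" * (1000 - gc))
        seqs = {"chr1": "".join(seq)}
        rep = self._setup(rates=[1.0, 2.0, 3.0, 4.0], seqs=seqs)
        assert rep.pearson_r_gc == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        rep = self._setup(rates=[2.0, 2.0, 2.0])
        assert np.isnan(rep.pearson_r_local_rate) or rep.pearson_r_local_rate == 0

    def test_uniform_repeats_near_expected(self, rng):
        """Repeats covering 10% of the genome, NCCM positions uniform:
        observed overlap tracks the expectation and the binomial test is
        typically unremarkable."""
        repeats = {"chr1": IntervalSet.from_pairs(
            "chr1", [(i * 10_000, i * 10_000 + 1_000) for i in range(10)])}
        obs, ps = [], []
        for seed in range(5):
            r = np.random.default_rng(seed)
            nccms = []
            for pos in r.integers(0, 100_000, size=400):
                v = SomaticVariant("s", "chr1", int(pos) + 1, "A", "T")
                nccms.append(AnnotatedVariant(v, 3.0, "noncoding_target",
                                              ("g0",), True))
            rep = self._setup(rates=[1.0, 2.0, 3.0], nccms=nccms, repeats=repeats)
            assert rep.repeat_overlap_expected == pytest.approx(0.10)
            obs.append(rep.repeat_overlap_observed)
            ps.append(rep.repeat_binomial_p)
        assert abs(np.median(obs) - 0.10) < 0.04
        assert np.median(ps) > 0.05

    def test_pearson_affine_invariance(self, rng):
        x = rng.normal(size=50)
        y = 2 * x + rng.normal(size=50)
        assert stats.pearsonr(3 * x + 7, y).statistic == pytest.approx(
            stats.pearsonr(x, y).statistic)
        assert stats.pearsonr(x, y).statistic == pytest.approx(pearson_naive(x, y))


class TestFilterSignatures:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos",
                                           "mutation_class", "signature"])

    def test_both_gates_inclusive(self):
        # SBS7 reaches 6% in one sample (gate 1) and appears in exactly
        # 10% of the 20-sample cohort (gate 2, inclusive)
        rows = []
        for i in range(94):
            rows.append((f"s0", "chr1", i, "coding", "SBS1"))
        for i in range(6):
            rows.append(("s0", "chr1", 200 + i, "coding", "SBS7"))
        rows.append(("s1", "chr1", 300, "coding", "SBS7"))
        retained = filter_signatures(self.frame(rows), n_samples=20)
        assert "SBS7" in retained

    def test_low_share_everywhere_dropped(self):
        rows = []
        for s in range(10):
            for i in range(96):
                rows.append((f"s{s}", "chr1", i, "coding", "SBS1"))
            for i in range(4):  # 4% share in every sample
                rows.append((f"s{s}", "chr1", 200 + i, "coding", "SBS7"))
        assert "SBS7" not in filter_signatures(self.frame(rows), n_samples=10)

    def test_rare_across_cohort_dropped(self):
        rows = [("s0", "chr1", i, "coding", "SBS7") for i in range(50)]
        rows += [("s0", "chr1", 100 + i, "coding", "SBS1") for i in range(50)]
        for s in range(1, 20):
            rows += [(f"s{s}", "chr1", i, "coding", "SBS1") for i in range(10)]
        assert "SBS7" not in filter_signatures(self.frame(rows), n_samples=20)

    def test_empty_input(self):
        assert filter_signatures(self.frame([])) == []


class TestSignatureShift:
    def test_balanced_table_null(self):
        df = simulate_signature_assignments(
            {"coding": {"S": 0.5, "T": 0.5}, "nccm": {"S": 0.5, "T": 0.5}},
            {"coding": 10, "nccm": 10}, np.random.default_rng(0))
        # overwrite draws with an exactly balanced table
        df.loc[df["mutation_class"] == "coding", "signature"] = ["S"] * 5 + ["T"] * 5
        df.loc[df["mutation_class"] == "nccm", "signature"] = ["S"] * 5 + ["T"] * 5
        res = signature_shift_test(df, "S")
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(1, 12, size=4))
            p = stats.fisher_exact([[a, b], [c, d]])[1]
            assert p == pytest.approx(fisher_point_two_sided(((a, b), (c, d))),
                                      abs=1e-10)

    def test_symmetry_under_class_swap_and_transpose(self, rng):
        df = simulate_signature_assignments(
            {"coding": {"S": 0.4, "T": 0.6}, "nccm": {"S": 0.15, "T": 0.85}},
            {"coding": 150, "nccm": 150}, rng)
        ab = signature_shift_test(df, "S", "coding", "nccm")
        ba = signature_shift_test(df, "S", "nccm", "coding")
        assert ab.p_value == pytest.approx(ba.p_value, rel=1e-9)
        t = np.asarray(ab.table)
        assert stats.fisher_exact(t)[1] == pytest.approx(
            stats.fisher_exact(t.T)[1], rel=1e-9)

    def test_planted_depletion_detected(self):
        """Signature at 40% of coding vs 10% of NCCM mutations, 2,000
        per class: depletion reported at overwhelming significance."""
        df = simulate_signature_assignments(
            {"coding": {"SBS1": 0.4, "SBS5": 0.6},
             "nccm": {"SBS1": 0.1, "SBS5": 0.9}},
            {"coding": 2000, "nccm": 2000}, np.random.default_rng(42))
        res = signature_shift_test(df, "SBS1", "coding", "nccm")
        assert res.p_value < 1e-6
        assert res.direction == "depleted in nccm"

    def test_empty_class_rejected(self):
        df = simulate_signature_assignments(
            {"coding": {"S": 1.0}}, {"coding": 5}, np.random.default_rng(0))
        with pytest.raises(ValueError):
            signature_shift_test(df, "S", "coding", "nccm")

    def test_doubling_rule_available(self, rng):
        df = simulate_signature_assignments(
            {"coding": {"S": 0.5, "T": 0.5}, "nccm": {"S": 0.3, "T": 0.7}},
            {"coding": 60, "nccm": 60}, rng)
        p_point = signature_shift_test(df, "S").p_value
        p_double = signature_shift_test(df, "S", two_sided_rule="double").p_value
        assert 0 < p_point <= 1 and 0 < p_double <= 1


class TestRegulatoryOverlap:
    def _nccms(self, positions):
        return [AnnotatedVariant(SomaticVariant("s", "chr1", p + 1, "A", "T"),
                                 2.0, "noncoding_target", ("g",), True)
                for p in positions]

    def test_saturating_track(self):
        tracks = {"dnase": {"chr1": IntervalSet.from_pairs("chr1", [(0, 10_000)])}}
        df = regulatory_overlap(self._nccms([5, 500, 5000]), tracks)
        assert df.iloc[0]["overlap_fraction"] == 1.0

    def test_empty_track_zero(self):
        df = regulatory_overlap(self._nccms([5]), {"h3k4me3": {}})
        assert df.iloc[0]["overlap_fraction"] == 0.0

    def test_uniform_positions_track_coverage(self, rng):
        tracks = {"t": {"chr1": IntervalSet.from_pairs(
            "chr1", [(i * 1000, i * 1000 + 200) for i in range(100)])}}  # 20%
        positions = rng.integers(0, 100_000, size=2000)
        df = regulatory_overlap(self._nccms(positions), tracks)
        assert abs(df.iloc[0]["overlap_fraction"] - 0.20) < 0.03
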