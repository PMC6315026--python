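import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crosstrait import sumstats_io as sio


# ---------------------------------------------------------------------------
# reading and record validation
# ---------------------------------------------------------------------------

class TestReadSumstats:
    def test_three_rows_roundtrip(self, toy_sumstats_frame, tmp_path):
        path = tmp_path / "ss.tsv"
        toy_sumstats_frame.to_csv(path, sep="\t", index=False)
        records = sio.read_sumstats(path)
        assert len(records) == 3
        for rec, (_, row) in zip(records, toy_sumstats_frame.iterrows()):
            assert rec.z == pytest.approx(row["BETA"] / row["SE"])
        assert records.skipped == []

    def test_z_derived_from_beta_se(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text("SNP\tCHR\tBP\tA1\tA2\tBETA\tSE\n"
                        "rs1\t1\t100\tA\tG\t0.1\t0.05\n")
        records = sio.read_sumstats(path)
        assert records[0].z == pytest.approx(2.0)
        assert records[0].p == pytest.approx(2 * stats.norm.sf(2.0))

    def test_missing_required_column_named_in_error(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text("SNP\tCHR\tBP\tA1\tA2\tBETA\n" "rs1\t1\t100\tA\tG\t0.1\n")
        with pytest.raises(sio.ConfigurationError, match="SE|Z"):
            sio.read_sumstats(path, dialect={"SE": "SE"})

    def test_unparseable_row_reported_not_dropped_silently(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text("SNP\tCHR\tBP\tA1\tA2\tZ\n"
                        "rs1\t1\t100\tA\tG\t1.5\n"
                        "rs2\t1\tnot_a_position\tA\tG\t1.0\n")
        with pytest.warns(UserWarning, match="skipped"):
            records = sio.read_sumstats(path)
        assert len(records) == 1
        assert len(records.skipped) == 1
        assert records.skipped[0][1] == "parse"

    def test_inconsistent_stats_flagged(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text("SNP\tCHR\tBP\tA1\tA2\tZ\tP\n"
                        "rs1\t1\t100\tA\tG\t5.0\t0.5\n")
        with pytest.warns(UserWarning):
            records = sio.read_sumstats(path)
        assert records.skipped[0][1] == "inconsistent_stats"

    def test_dialect_maps_foreign_header(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text("MarkerName\tchr\tposition\teffect_allele\tother_allele\tzscore\n"
                        "rs1\t1\t100\tA\tG\t1.0\n")
        records = sio.read_sumstats(path, dialect={
            "SNP": "MarkerName", "CHR": "chr", "BP": "position",
            "A1": "effect_allele", "A2": "other_allele", "Z": "zscore"})
        assert records[0].variant.snp_id == "rs1"

    def test_indel_flagged_not_error(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text("SNP\tCHR\tBP\tA1\tA2\tZ\n" "rs1\t1\t100\tAT\tG\t1.0\n")
        records = sio.read_sumstats(path)
        assert records[0].variant.is_indel


class TestRecordInvariants:
    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            sio.VariantRecord("rs1", "1", 100, "A", "A")

    def test_maf_range_enforced(self):
        with pytest.raises(ValueError):
            sio.VariantRecord("rs1", "1", 100, "A", "G", maf=0.7)

    def test_strand_ambiguity(self):
        assert sio.VariantRecord("rs1", "1", 100, "A", "T").is_strand_ambiguous
        assert sio.VariantRecord("rs2", "1", 100, "C", "G").is_strand_ambiguous
        assert not sio.VariantRecord("rs3", "1", 100, "A", "G").is_strand_ambiguous

    def test_z_beta_se_consistency_enforced(self):
        v = sio.VariantRecord("rs1", "1", 100, "A", "G")
        with pytest.raises(ValueError, match="inconsistent"):
            sio.SummaryStatRecord(variant=v, beta=0.1, se=0.05, z=5.0)

    def test_p_z_consistency_enforced(self):
        v = sio.VariantRecord("rs1", "1", 100, "A", "G")
        with pytest.raises(ValueError, match="inconsistent"):
            sio.SummaryStatRecord(variant=v, z=5.0, p=0.5)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _pair_frames():
    base = pd.DataFrame({
        "SNP": ["rs1", "rs2", "rs3", "rs4", "rs5", "rs6"],
        "CHR": ["1"] * 5 + ["6"],
        "BP": [1000, 2000, 3000, 4000, 5000, 30_000_000],
        "A1": ["A", "A", "C", "A", "A", "A"],
        "A2": ["G", "T", "T", "G", "G", "G"],
        "BETA": [0.1, 0.1, 0.1, 0.1, 0.1, 0.1],
        "SE": [0.05] * 6,
        "Z": [2.0] * 6,
        "P": [2 * stats.norm.sf(2.0)] * 6,
        "N_CAS": [1000] * 6,
        "N_CON": [1000] * 6,
        "MAF": [0.2] * 6,
        "INFO": [0.99, 0.99, 0.99, 0.85, 0.99, 0.99],
    })
    other = base.copy()
    # rs5 appears allele-swapped in trait B
    other.loc[other["SNP"] == "rs5", ["A1", "A2"]] = ["G", "A"]
    reference = pd.DataFrame({
        "SNP": ["rs1", "rs2", "rs3", "rs4", "rs5", "rs6"],
        "A1": ["A", "A", "C", "A", "A", "A"],
        "A2": ["G", "T", "T", "G", "G", "G"],
        "MAF": [0.2, 0.2, 0.2, 0.2, 0.2, 0.2],
    })
    return base, other, reference


class TestHarmonizePair:
    def test_filters_and_reasons(self):
        a, b, ref = _pair_frames()
        fa, fb, report = sio.harmonize_pair(a, b, ref)
        # rs2 (A/T) ambiguous, rs3 (C/T vs ref?) fine, rs4 info, rs6 hla
        assert report.n_removed_by_reason["info"] == 1
        assert report.n_removed_by_reason["strand_ambiguous"] == 1
        assert report.n_removed_by_reason["hla"] == 1
        assert report.retained == {"rs1", "rs3", "rs5"}
        report.validate()

    def test_low_info_removed(self):
        a, b, ref = _pair_frames()
        _, _, report = sio.harmonize_pair(a, b, ref)
        assert "rs4" in report.removed_by_reason["info"]

    def test_swapped_alleles_flip_sign_preserve_p(self):
        a, b, ref = _pair_frames()
        fa, fb, _ = sio.harmonize_pair(a, b, ref)
        rec_b = fb[fb["SNP"] == "rs5"].iloc[0]
        rec_a = fa[fa["SNP"] == "rs5"].iloc[0]
        assert rec_b["Z"] == pytest.approx(-2.0)
        assert rec_b["BETA"] == pytest.approx(-0.1)
        assert rec_a["Z"] == pytest.approx(2.0)
        assert rec_b["P"] == pytest.approx(rec_a["P"])
        assert (rec_b["A1"], rec_b["A2"]) == ("A", "G")

    def test_strand_flip_resolved(self):
        a, b, ref = _pair_frames()
        # rs1 reported on the other strand in trait B: A/G -> T/C
        b.loc[b["SNP"] == "rs1", ["A1", "A2"]] = ["T", "C"]
        fa, fb, report = sio.harmonize_pair(a, b, ref)
        rec = fb[fb["SNP"] == "rs1"].iloc[0]
        assert rec["Z"] == pytest.approx(2.0)  # flip without swap: no sign change
        assert (rec["A1"], rec["A2"]) == ("A", "G")

    def test_allele_mismatch_removed(self):
        a, b, ref = _pair_frames()
        b.loc[b["SNP"] == "rs1", ["A1", "A2"]] = ["A", "C"]
        _, _, report = sio.harmonize_pair(a, b, ref)
        assert "rs1" in report.removed_by_reason["allele_mismatch"]

    def test_not_in_both(self):
        a, b, ref = _pair_frames()
        b = b[b["SNP"] != "rs1"]
        _, _, report = sio.harmonize_pair(a, b, ref)
        assert "rs1" in report.removed_by_reason["not_in_both"]

    def test_not_in_reference_and_ref_maf(self):
        a, b, ref = _pair_frames()
        ref = ref[ref["SNP"] != "rs1"].copy()
        ref.loc[ref["SNP"] == "rs3", "MAF"] = 0.01
        _, _, report = sio.harmonize_pair(a, b, ref)
        assert "rs1" in report.removed_by_reason["not_in_reference"]
        assert "rs3" in report.removed_by_reason["reference_maf"]

    def test_empty_intersection_raises(self):
        a, b, ref = _pair_frames()
        a["INFO"] = 0.5
        with pytest.raises(sio.HarmonizationError):
            sio.harmonize_pair(a, b, ref)

    def test_idempotent(self):
        a, b, ref = _pair_frames()
        fa1, fb1, r1 = sio.harmonize_pair(a, b, ref)
        fa2, fb2, r2 = sio.harmonize_pair(fa1, fb1, ref)
        assert r2.retained == r1.retained
        pd.testing.assert_frame_equal(fa1.reset_index(drop=True),
                                      fa2.reset_index(drop=True))
        pd.testing.assert_frame_equal(fb1.reset_index(drop=True),
                                      fb2.reset_index(drop=True))

    def test_abs_z_preserved(self):
        a, b, ref = _pair_frames()
        fa, fb, _ = sio.harmonize_pair(a, b, ref)
        for frame, source in ((fa, a), (fb, b)):
            src = source.set_index("SNP")["Z"]
            for snp, z in zip(frame["SNP"], frame["Z"]):
                assert abs(z) == pytest.approx(abs(src[snp]))

    def test_each_snp_one_reason(self):
        a, b, ref = _pair_frames()
        a.loc[a["SNP"] == "rs4", ["A1", "A2"]] = ["A", "T"]  # indelless double-fail
        _, _, report = sio.harmonize_pair(a, b, ref)
        all_removed = [s for ids in report.removed_by_reason.values() for s in ids]
        assert len(all_removed) == len(set(all_removed))
        report.validate()

    def test_accepts_record_lists(self):
        a, b, ref = _pair_frames()
        ra = sio.frame_to_records(a)
        rb = sio.frame_to_records(b)
        fa, fb, report = sio.harmonize_pair(ra, rb, ref)
        assert report.retained == {"rs1", "rs3", "rs5"}


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Independent full enumeration with exact combinatorics."""
    from fractions import Fraction

    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    probs = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        probs[h] = (Fraction(2) ** h
                    * Fraction(math.factorial(n),
                               math.factorial(hom_minor) * math.factorial(hom_major)
                               * math.factorial(h)))
    total = sum(probs.values())
    p_obs = probs[n_Aa] / total
    return float(sum(p for p in (v / total for v in probs.values()) if p <= p_obs))


class TestHweExactTest:
    def test_perfect_proportions(self):
        assert sio.hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_monomorphic_convention(self):
        assert sio.hwe_exact_test(100, 0, 0) == 1.0

    def test_small_table_matches_enumeration(self):
        assert sio.hwe_exact_test(3, 5, 2) == pytest.approx(
            hwe_enumeration_oracle(3, 5, 2), abs=1e-12)

    def test_extreme_deviation_tiny_p(self):
        p = sio.hwe_exact_test(50, 0, 50)
        assert p == pytest.approx(hwe_enumeration_oracle(50, 0, 50), rel=1e-9)
        assert p < 1e-5

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sio.hwe_exact_test(-1, 2, 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sio.hwe_exact_test(0, 0, 0)

    @given(st.integers(0, 17), st.integers(0, 17), st.integers(0, 16))
    @settings(max_examples=150, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c):
        if a + b + c == 0:
            return
        assert sio.hwe_exact_test(a, b, c) == pytest.approx(
            hwe_enumeration_oracle(a, b, c), abs=1e-12)


# ---------------------------------------------------------------------------
# genotype QC
# ---------------------------------------------------------------------------

class TestQcGenotypes:
    def _matrix(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(100, 25)).astype(float)
        # SNP 0: perfect HWE proportions
        geno[:, 0] = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])
        # SNP 1: extreme HWE deviation
        geno[:, 1] = np.repeat([0.0, 2.0], [50, 50])
        # SNP 2: 94/100 called
        geno[:6, 2] = np.nan
        # SNP 3: rare
        geno[:, 3] = 0.0
        geno[0, 3] = 1.0
        # remaining SNPs: HWE draws so they pass
        for j in range(4, 25):
            f = rng.uniform(0.2, 0.5)
            geno[:, j] = rng.binomial(1, f, 100) + rng.binomial(1, f, 100)
        return geno

    def test_reason_assignment(self):
        report = sio.qc_genotypes(self._matrix())
        assert "snp2" in report.removed_by_reason["call_rate"]
        assert "snp3" in report.removed_by_reason["maf"]
        assert "snp1" in report.removed_by_reason["hwe"]
        assert "snp0" in report.retained
        report.validate()

    def test_individuals_removed_first(self):
        geno = self._matrix()
        geno[0, :10] = np.nan  # individual 0 call rate 60%
        report = sio.qc_genotypes(geno)
        assert report.n_individuals_removed == 1

    def test_all_individuals_removed_raises(self):
        geno = np.full((5, 30), np.nan)
        geno[:, 0] = 1.0
        with pytest.raises(sio.DegenerateInputError):
            sio.qc_genotypes(geno)

    def test_hwe_in_controls_only(self):
        geno = np.zeros((100, 20))
        rng = np.random.default_rng(1)
        for j in range(20):
            geno[:50, j] = rng.binomial(2, 0.4, 50)          # controls in HWE
        geno[50:, :] = np.repeat([[0.0, 2.0]], 10, axis=1)[:, :20]  # cases deviate
        geno[50:75, :] = 0.0
        geno[75:, :] = 2.0
        report = sio.qc_genotypes(geno, controls=range(50))
        assert "hwe" not in report.n_removed_by_reason


# ---------------------------------------------------------------------------
# genomic inflation
# ---------------------------------------------------------------------------

class TestGenomicInflation:
    def test_null_median_gives_unity(self):
        chi2 = np.full(1000, stats.chi2.ppf(0.5, 1))
        res = sio.genomic_inflation(chi2, 1000, 1000)
        assert res.lambda_gc == pytest.approx(1.0, abs=1e-12)

    def test_lambda1000_fixed_point(self):
        chi2 = np.full(1000, 1.10 * stats.chi2.ppf(0.5, 1))
        res = sio.genomic_inflation(chi2, 1000, 1000)
        assert res.lambda_gc == pytest.approx(1.10)
        assert res.lambda_1000 == pytest.approx(1.10)

    def test_lambda1000_rescaling(self):
        chi2 = np.full(1000, 1.10 * stats.chi2.ppf(0.5, 1))
        res = sio.genomic_inflation(chi2, 4000, 4000)
        assert res.lambda_1000 == pytest.approx(1.025)

    def test_lambda1000_closer_to_one(self):
        rng = np.random.default_rng(2)
        chi2 = 1.3 * rng.chisquare(1, size=5000)
        res = sio.genomic_inflation(chi2, 5000, 5000)
        assert res.lambda_gc > 1
        assert abs(res.lambda_1000 - 1) < abs(res.lambda_gc - 1)

    def test_small_input_warns_in_result(self):
        res = sio.genomic_inflation(np.ones(50), 1000, 1000)
        assert res.warnings

    def test_uses_least_significant_fraction(self):
        # planting huge chi2 in the top 10% must not move the estimate
        base = np.full(900, stats.chi2.ppf(0.5, 1))
        spiked = np.concatenate([base, np.full(100, 500.0)])
        res = sio.genomic_inflation(spiked, 1000, 1000, quantile_fraction=0.9)
        assert res.n_snps_used == 900
        assert res.lambda_gc == pytest.approx(1.0, abs=1e-12)
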