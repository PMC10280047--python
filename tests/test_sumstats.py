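"""Summary-statistics I/O, filtering, harmonization and standardization."""

import numpy as np
import pandas as pd
import pytest

from transprs.sumstats import (
    DEFAULT_HLA_REGION,
    SummaryStats,
    exclude_region,
    harmonize_alleles,
    read_sumstats,
    restrict_to_panel,
    standardize_effects,
    write_sumstats,
)


def make_stats(rows):
    """rows: list of (id, chrom, pos, ea, oa, eaf, beta)."""
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "effect_allele", "other_allele", "eaf", "beta"])
    df["se"] = 0.01
    df["p"] = 0.5
    df["n"] = 10_000
    return SummaryStats(df)


def make_ref(rows):
    """rows: list of (id, allele_a, allele_b); allele_b is counted."""
    return pd.DataFrame(rows, columns=["variant_id", "allele_a", "allele_b"])


class TestReadWrite:
    def test_round_trip_preserves_values_exactly(self, gwas_bundle, tmp_path):
        _, _, stats = gwas_bundle
        usable = stats.usable()
        path = tmp_path / "ss.tsv"
        write_sumstats(usable, path)
        back = read_sumstats(path)
        assert len(back) == len(usable)
        assert np.allclose(back.df["beta"], usable.df["beta"], atol=1e-12, rtol=0)
        assert np.allclose(back.df["se"], usable.df["se"], atol=1e-12, rtol=0)

    def test_well_formed_fixture_fully_typed(self, tmp_path):
        path = tmp_path / "five.tsv"
        path.write_text(
            "SNP\tA1\tA2\tFreq\tb\tse\tp\tN\n"
            + "".join(f"rs{i}\tA\tG\t0.{i + 1}\t0.0{i}\t0.01\t0.5\t1000\n" for i in range(5))
        )
        stats = read_sumstats(path)
        assert len(stats) == 5
        assert stats.df["n"].dtype.kind in "if"
        assert stats.df["beta"].tolist() == [0.00, 0.01, 0.02, 0.03, 0.04]

    def test_zero_se_row_dropped_and_reported(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "SNP\tA1\tA2\tFreq\tb\tse\tp\tN\n"
            "rs1\tA\tG\t0.3\t0.1\t0.01\t0.5\t1000\n"
            "rs2\tA\tG\t0.3\t0.1\t0\t0.5\t1000\n"
        )
        with pytest.warns(UserWarning, match="dropped"):
            stats = read_sumstats(path)
        assert len(stats) == 1
        assert stats.read_report["dropped_malformed"] == 1

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = tmp_path / "noc.tsv"
        path.write_text("SNP\tA1\tA2\tFreq\tb\tse\tp\nrs1\tA\tG\t0.3\t0.1\t0.01\t0.5\n")
        with pytest.raises(ValueError, match="'N'"):
            read_sumstats(path)

    def test_non_acgt_allele_dropped_with_count(self, tmp_path):
        path = tmp_path / "indel.tsv"
        path.write_text(
            "SNP\tA1\tA2\tFreq\tb\tse\tp\tN\n"
            "rs1\tA\tG\t0.3\t0.1\t0.01\t0.5\t1000\n"
            "rs2\tI\tD\t0.3\t0.1\t0.01\t0.5\t1000\n"
        )
        with pytest.warns(UserWarning):
            stats = read_sumstats(path)
        assert len(stats) == 1
        assert stats.read_report["dropped_bad_allele"] == 1


class TestRestrict:
    def test_identity_when_all_ids_kept(self):
        stats = make_stats([(f"rs{i}", "1", i * 10, "A", "G", 0.3, 0.1) for i in range(1, 6)])
        out = restrict_to_panel(stats, set(stats.df["variant_id"]))
        assert out.df["variant_id"].tolist() == stats.df["variant_id"].tolist()

    def test_disjoint_ids_error(self):
        stats = make_stats([("rs1", "1", 10, "A", "G", 0.3, 0.1)])
        with pytest.raises(ValueError, match="nothing to train"):
            restrict_to_panel(stats, {"rsX"})

    def test_empty_keep_set_error(self):
        stats = make_stats([("rs1", "1", 10, "A", "G", 0.3, 0.1)])
        with pytest.raises(ValueError):
            restrict_to_panel(stats, set())

    def test_subset_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(0)
        stats = make_stats([(f"rs{i}", "1", i * 10, "A", "G", 0.3, 0.1) for i in range(1000)])
        keep = set(rng.choice([f"rs{i}" for i in range(1000)], size=600, replace=False))
        out = restrict_to_panel(stats, keep)
        assert len(out) == 600
        assert set(out.df["variant_id"]) == keep
        # order preserved
        assert out.df["variant_id"].tolist() == [v for v in stats.df["variant_id"] if v in keep]


class TestExcludeRegion:
    def test_hla_interval_removes_inside_variants(self):
        rows = [
            ("rs1", "6", 24_999_999, "A", "G", 0.3, 0.1),
            ("rs2", "6", 25_000_000, "A", "G", 0.3, 0.1),
            ("rs3", "6", 30_000_000, "A", "G", 0.3, 0.1),
            ("rs4", "6", 34_000_000, "A", "G", 0.3, 0.1),
            ("rs5", "6", 34_000_001, "A", "G", 0.3, 0.1),
            ("rs6", "7", 30_000_000, "A", "G", 0.3, 0.1),
        ]
        out = exclude_region(make_stats(rows), *DEFAULT_HLA_REGION)
        # boundaries are inclusive: rs2 and rs4 excluded along with rs3
        assert out.df["variant_id"].tolist() == ["rs1", "rs5", "rs6"]

    def test_absent_chromosome_is_identity(self):
        stats = make_stats([("rs1", "1", 30_000_000, "A", "G", 0.3, 0.1)])
        out = exclude_region(stats, "6", 25_000_000, 34_000_000)
        assert len(out) == 1

    def test_inverted_interval_rejected(self):
        stats = make_stats([("rs1", "6", 10, "A", "G", 0.3, 0.1)])
        with pytest.raises(ValueError):
            exclude_region(stats, "6", 100, 10)


class TestHarmonize:
    def test_swapped_alleles_negate_beta_and_complement_eaf(self):
        stats = make_stats([("rs1", "1", 10, "A", "G", 0.3, 0.10)])
        out, rep = harmonize_alleles(stats, make_ref([("rs1", "A", "G")]))
        # reference counts G; stats effect allele is A -> swap
        assert out.df.loc[0, "beta"] == pytest.approx(-0.10)
        assert out.df.loc[0, "eaf"] == pytest.approx(0.7)
        assert out.df.loc[0, "effect_allele"] == "G"
        assert rep.allele_swapped == 1

    def test_strand_flip_keeps_beta(self):
        stats = make_stats([("rs1", "1", 10, "A", "G", 0.3, 0.10)])
        out, rep = harmonize_alleles(stats, make_ref([("rs1", "C", "T")]))
        # stats (A,G) complements to (T,C): effect allele T = counted allele
        assert out.df.loc[0, "beta"] == pytest.approx(0.10)
        assert rep.strand_flipped == 1

    def test_high_maf_ambiguous_pair_dropped(self):
        stats = make_stats([("rs1", "1", 10, "A", "T", 0.48, 0.10)])
        out, rep = harmonize_alleles(stats, make_ref([("rs1", "T", "A")]), ambiguity_maf=0.40)
        assert len(out) == 0
        assert rep.ambiguous_dropped == 1

    def test_low_maf_ambiguous_pair_resolved_by_frequency(self):
        stats = make_stats([("rs1", "1", 10, "A", "T", 0.10, 0.10)])
        ref = make_ref([("rs1", "T", "A")])
        # reference frequency of counted allele A near 0.1 -> same orientation
        out, _ = harmonize_alleles(stats, ref, ref_freq=np.array([0.12]))
        assert out.df.loc[0, "beta"] == pytest.approx(0.10)
        # reference frequency near 0.9 -> opposite orientation, sign negated
        out2, _ = harmonize_alleles(stats, ref, ref_freq=np.array([0.88]))
        assert out2.df.loc[0, "beta"] == pytest.approx(-0.10)

    def test_unmatched_and_duplicates_counted(self):
        stats = make_stats(
            [
                ("rs1", "1", 10, "A", "G", 0.3, 0.1),
                ("rs1", "1", 10, "A", "G", 0.3, 0.1),
                ("rs2", "1", 20, "A", "G", 0.3, 0.1),
                ("rs3", "1", 30, "A", "C", 0.3, 0.1),
            ]
        )
        ref = make_ref([("rs1", "A", "G"), ("rs3", "A", "G")])
        out, rep = harmonize_alleles(stats, ref)
        assert rep.duplicate_dropped == 1
        assert rep.unmatched_dropped == 2  # rs2 absent, rs3 allele mismatch
        assert rep.total == 4

    def test_report_counts_partition_input(self, gwas_bundle):
        _, _, stats = gwas_bundle
        ref = stats.df[["variant_id", "other_allele", "effect_allele"]].rename(
            columns={"other_allele": "allele_a", "effect_allele": "allele_b"}
        )
        out, rep = harmonize_alleles(stats, ref, ref_freq=stats.df["eaf"].to_numpy())
        assert rep.total == len(stats)
        assert rep.allele_swapped == 0

    def test_idempotent(self, gwas_bundle):
        _, _, stats = gwas_bundle
        ref = pd.DataFrame(
            {
                "variant_id": stats.df["variant_id"],
                "allele_a": stats.df["effect_allele"],  # force swaps on first pass
                "allele_b": stats.df["other_allele"],
            }
        )
        once, rep1 = harmonize_alleles(stats, ref, ref_freq=1 - stats.df["eaf"].to_numpy())
        twice, rep2 = harmonize_alleles(once, ref, ref_freq=1 - stats.df["eaf"].to_numpy())
        assert rep2.allele_swapped == 0
        assert rep2.strand_flipped == 0
        assert rep2.ambiguous_dropped == 0
        assert np.allclose(once.df["beta"], twice.df["beta"], atol=0, rtol=0)

    def test_double_negation_round_trip(self):
        rows = [(f"rs{i}", "1", i * 10, "A", "G", 0.2 + 0.01 * i, 0.05 * i) for i in range(1, 11)]
        stats = make_stats(rows)
        ref_fwd = make_ref([(f"rs{i}", "A", "G") for i in range(1, 11)])
        direct, _ = harmonize_alleles(stats, ref_fwd)
        # negate betas and swap allele columns, then harmonize: same result
        flipped = stats.df.copy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        flipped[["effect_allele", "other_allele"]] = flipped[["other_allele", "effect_allele"]].to_numpy()
        back, _ = harmonize_alleles(SummaryStats(flipped), ref_fwd)
        assert np.allclose(direct.df["beta"], back.df["beta"], atol=1e-12, rtol=0)
        assert np.allclose(direct.df["eaf"], back.df["eaf"], atol=1e-12, rtol=0)


class TestStandardize:
    def test_arithmetic(self):
        stats = make_stats([("rs1", "1", 10, "A", "G", 0.3, 0.1)])
        stats.df["se"] = 0.05
        stats.df["n"] = 10_000
        assert standardize_effects(stats)[0] == pytest.approx(0.02)

    def test_zero_beta_gives_zero(self):
        stats = make_stats([("rs1", "1", 10, "A", "G", 0.3, 0.0)])
        assert standardize_effects(stats)[0] == 0.0

    def test_heterogeneous_n_warns(self):
        stats = make_stats([("rs1", "1", 10, "A", "G", 0.3, 0.1), ("rs2", "1", 20, "A", "G", 0.3, 0.1)])
        stats.df.loc[1, "n"] = 100_000
        with pytest.warns(UserWarning, match="sample size"):
            standardize_effects(stats)

    def test_matches_marginal_correlation_identity(self, gwas_bundle):
        panel, _, stats = gwas_bundle
        std = standardize_effects(stats.usable())
        x = panel.dosages.astype(float)
        y = panel.phenotype
        r = np.array(
            [np.corrcoef(x[:, j], y)[0, 1] for j in range(panel.n_variants)]
        )
        assert np.corrcoef(std, r)[0, 1] > 0.99
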