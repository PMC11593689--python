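"""Summary-statistics I/O, validation and harmonization."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from medimr import estimators
from medimr.sumstats_io import (ConfigError, EmptyInputError, EmptyOverlapError,
                                harmonize, kept_pairs, or_ci_to_logscale,
                                read_sumstats, write_sumstats)

from conftest import make_table


def _write_tsv(path, rows, header="SNP\tCHR\tBP\tEA\tOA\tBETA\tSE\tP\tEAF\tN"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestReadWrite:
    def test_wellformed_tsv_read_order_preserved(self, tmp_path):
        f = tmp_path / "x.tsv"
        _write_tsv(f, [
            "rs3\t1\t100\tA\tG\t0.1\t0.01\t1e-9\t0.3\t1000",
            "rs1\t2\t200\tC\tT\t-0.2\t0.02\t1e-8\t0.4\t1000",
            "rs2\t3\t300\tG\tA\t0.05\t0.03\t0.5\tNA\tNA",
        ])
        t = read_sumstats(f)
        assert t.n_snps == 3
        assert list(t.df["snp_id"]) == ["rs3", "rs1", "rs2"]
        assert pd.isna(t.df["eaf"].iloc[2])

    def test_invalid_rows_rejected_with_row_numbers(self, tmp_path):
        f = tmp_path / "x.tsv"
        _write_tsv(f, [
            "rs1\t1\t100\tA\tG\t0.1\t0\t1e-9\t0.3\t1000",      # se = 0
            "rs2\t1\t200\tA\tG\t0.1\t0.01\t1.5\t0.3\t1000",    # p > 1
            "rs3\t1\t300\tA\tA\t0.1\t0.01\t0.5\t0.3\t1000",    # EA == OA
            "rs4\t1\t400\tA\tG\t0.1\t0.01\t0.5\t0.3\t1000",
        ])
        t = read_sumstats(f)
        assert t.n_snps == 1
        assert t.df["snp_id"].iloc[0] == "rs4"
        assert any("row 1" in line for line in t.validation_log)
        assert any("se" in line for line in t.validation_log)

    def test_lowercase_alleles_normalized(self, tmp_path):
        f = tmp_path / "x.tsv"
        _write_tsv(f, ["rs1\t1\t100\ta\tg\t0.1\t0.01\t1e-9\t0.3\t1000"])
        t = read_sumstats(f)
        assert t.df["effect_allele"].iloc[0] == "A"
        assert t.df["other_allele"].iloc[0] == "G"

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        f = tmp_path / "x.tsv"
        f.write_text("SNP\tCHR\tBP\n" "rs1\t1\t100\n")
        with pytest.raises(ConfigError, match="BETA"):
            read_sumstats(f)

    def test_all_rows_invalid_is_empty_input_error(self, tmp_path):
        f = tmp_path / "x.tsv"
        _write_tsv(f, ["rs1\t1\t100\tA\tG\t0.1\t-1\t1e-9\t0.3\t1000"])
        with pytest.raises(EmptyInputError):
            read_sumstats(f)

    def test_comma_delimiter_autodetected(self, tmp_path):
        f = tmp_path / "x.csv"
        f.write_text("SNP,CHR,BP,EA,OA,BETA,SE,P,EAF,N\nrs1,1,100,A,G,0.1,0.01,1e-9,0.3,1000\n")
        assert read_sumstats(f).n_snps == 1

    def test_custom_column_map(self, tmp_path):
        f = tmp_path / "x.tsv"
        f.write_text("rsid\tchr\tposition\ta1\ta2\teffect\tstderr\tpvalue\n"
                     "rs1\t1\t100\tA\tG\t0.1\t0.01\t1e-9\n")
        t = read_sumstats(f, column_map={
            "snp_id": "rsid", "chrom": "chr", "pos": "position",
            "effect_allele": "a1", "other_allele": "a2",
            "beta": "effect", "se": "stderr", "pval": "pvalue"})
        assert t.n_snps == 1 and pd.isna(t.df["eaf"].iloc[0])

    def test_round_trip_identity(self, tmp_path, rng):
        recs = [{"beta": rng.normal(), "se": float(rng.uniform(0.001, 0.1)),
                 "pval": float(rng.uniform(1e-12, 1)),
                 "eaf": float(rng.uniform(0.01, 0.99))} for _ in range(5)]
        recs[2]["eaf"] = np.nan  # missing eaf survives as NA
        t = make_table(recs)
        f = tmp_path / "rt.tsv"
        write_sumstats(t, f)
        assert "NA" in f.read_text()
        back = read_sumstats(f, trait_type=t.trait_type)
        pd.testing.assert_frame_equal(back.df, t.df)

    def test_round_trip_empty_table(self, tmp_path):
        t = make_table([{}]).subset(np.array([False]))
        f = tmp_path / "empty.tsv"
        write_sumstats(t, f)
        with pytest.raises(EmptyInputError):
            read_sumstats(f)  # header-only file has zero valid rows


class TestHarmonize:
    def test_identical_orientation_kept_as_is(self):
        e = make_table([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        o = make_table([{"effect_allele": "A", "other_allele": "G", "beta": 0.05}])
        h = harmonize(e, o)
        assert h["action"].iloc[0] == "kept_as_is"
        assert h["beta_out"].iloc[0] == 0.05

    def test_swapped_alleles_flip_sign_and_eaf(self):
        e = make_table([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        o = make_table([{"effect_allele": "G", "other_allele": "A",
                         "beta": 0.05, "eaf": 0.3}])
        h = harmonize(e, o)
        assert h["action"].iloc[0] == "flipped"
        assert h["beta_out"].iloc[0] == -0.05
        assert h["eaf_out"].iloc[0] == pytest.approx(0.7)

    def test_strand_complement_resolved(self):
        e = make_table([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        o = make_table([{"effect_allele": "T", "other_allele": "C", "beta": 0.05}])
        h = harmonize(e, o)
        assert h["action"].iloc[0] == "kept_as_is"
        assert h["beta_out"].iloc[0] == 0.05

    def test_strand_complement_and_swap(self):
        e = make_table([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        o = make_table([{"effect_allele": "C", "other_allele": "T", "beta": 0.05}])
        h = harmonize(e, o)
        assert h["action"].iloc[0] == "flipped"
        assert h["beta_out"].iloc[0] == -0.05

    def test_irreconcilable_alleles_dropped(self):
        e = make_table([{"effect_allele": "A", "other_allele": "G"}])
        o = make_table([{"effect_allele": "A", "other_allele": "C"}])
        assert harmonize(e, o)["action"].iloc[0] == "dropped_mismatch"

    def test_palindromic_ambiguous_frequency_dropped(self):
        # eaf 0.50 lies inside [0.42, 0.58] under drop_ambiguous
        e = make_table([{"effect_allele": "A", "other_allele": "T", "eaf": 0.50}])
        o = make_table([{"effect_allele": "A", "other_allele": "T", "eaf": 0.50}])
        h = harmonize(e, o, "drop_ambiguous", 0.42)
        assert h["action"].iloc[0] == "dropped_palindromic"

    def test_palindromic_clear_frequency_kept(self):
        e = make_table([{"effect_allele": "A", "other_allele": "T", "eaf": 0.10}])
        o = make_table([{"effect_allele": "A", "other_allele": "T",
                         "beta": 0.05, "eaf": 0.12}])
        h = harmonize(e, o, "drop_ambiguous", 0.42)
        assert h["action"].iloc[0] == "kept_as_is"
        assert h["beta_out"].iloc[0] == 0.05

    def test_palindromic_opposite_frequency_strand_flipped(self):
        # outcome reports the other strand: its A-frequency is 1 - 0.10
        e = make_table([{"effect_allele": "A", "other_allele": "T", "eaf": 0.10}])
        o = make_table([{"effect_allele": "A", "other_allele": "T",
                         "beta": 0.05, "eaf": 0.90}])
        h = harmonize(e, o, "drop_ambiguous", 0.42)
        assert h["action"].iloc[0] == "flipped"
        assert h["beta_out"].iloc[0] == -0.05

    def test_palindromic_drop_all_policy(self):
        e = make_table([{"effect_allele": "C", "other_allele": "G", "eaf": 0.1}])
        o = make_table([{"effect_allele": "C", "other_allele": "G", "eaf": 0.1}])
        assert harmonize(e, o, "drop_all")["action"].iloc[0] == "dropped_palindromic"

    def test_palindromic_missing_eaf_dropped(self):
        e = make_table([{"effect_allele": "A", "other_allele": "T", "eaf": np.nan}])
        o = make_table([{"effect_allele": "A", "other_allele": "T", "eaf": 0.1}])
        assert harmonize(e, o)["action"].iloc[0] == "dropped_palindromic"

    def test_empty_overlap_raises(self):
        e = make_table([{"snp_id": "rsA"}])
        o = make_table([{"snp_id": "rsB"}])
        with pytest.raises(EmptyOverlapError):
            harmonize(e, o)

    def test_idempotence(self, rng):
        """Harmonizing an already-harmonized pair set changes nothing."""
        e = make_table([
            {"snp_id": f"rs{i}", "effect_allele": "A", "other_allele": "G",
             "beta": float(rng.normal()), "eaf": float(rng.uniform(0.05, 0.95))}
            for i in range(8)])
        o = make_table([
            {"snp_id": f"rs{i}", "effect_allele": "G", "other_allele": "A",
             "beta": float(rng.normal()), "eaf": float(rng.uniform(0.05, 0.95))}
            for i in range(8)])
        h1 = kept_pairs(harmonize(e, o))
        # rebuild tables from the harmonized frame and harmonize again
        e2 = make_table([
            {"snp_id": r.snp_id, "effect_allele": r.effect_allele,
             "other_allele": r.other_allele, "beta": r.beta_exp,
             "se": r.se_exp, "pval": r.pval_exp, "eaf": r.eaf}
            for r in h1.itertuples()])
        o2 = make_table([
            {"snp_id": r.snp_id, "effect_allele": r.effect_allele,
             "other_allele": r.other_allele, "beta": r.beta_out,
             "se": r.se_out, "pval": r.pval_out, "eaf": r.eaf_out}
            for r in h1.itertuples()])
        h2 = kept_pairs(harmonize(e2, o2))
        assert list(h2["action"]) == ["kept_as_is"] * len(h1)
        np.testing.assert_allclose(h2["beta_out"], h1["beta_out"], rtol=0, atol=0)
        np.testing.assert_allclose(h2["beta_exp"], h1["beta_exp"], rtol=0, atol=0)

    def test_frame_invariance_of_downstream_estimate(self, rng):
        """Recoding BOTH tables (swap alleles, negate beta, eaf->1-eaf)
        leaves the IVW estimate identical to machine precision."""
        n = 10
        recs_e = [{"snp_id": f"rs{i}", "beta": float(rng.normal(0.1, 0.02)),
                   "eaf": float(rng.uniform(0.05, 0.95))} for i in range(n)]
        recs_o = [{"snp_id": f"rs{i}", "beta": float(rng.normal(0.03, 0.01)),
                   "eaf": float(rng.uniform(0.05, 0.95))} for i in range(n)]
        e, o = make_table(recs_e), make_table(recs_o)

        def recode(t):
            d = t.df.copy()
            d[["effect_allele", "other_allele"]] = d[["other_allele", "effect_allele"]].to_numpy()
            d["beta"] = -d["beta"]
            d["eaf"] = 1 - d["eaf"]
            from medimr.sumstats_io import SumStatsTable
            return SumStatsTable(t.trait_id, t.trait_type, d)

        est1 = estimators.ivw(kept_pairs(harmonize(e, o)), "fixed")
        est2 = estimators.ivw(kept_pairs(harmonize(recode(e), recode(o))), "fixed")
        assert est1.beta == pytest.approx(est2.beta, abs=0, rel=1e-15)
        assert est1.se == pytest.approx(est2.se, abs=0, rel=1e-15)


class TestOrCiToLogscale:
    def test_null_or(self):
        assert or_ci_to_logscale(1.0, 1.0, 1.0) == (0.0, 0.0)

    def test_printed_glucosamine_ci(self):
        beta, se = or_ci_to_logscale(0.888, 0.824, 0.958)
        assert beta == pytest.approx(-0.1188, abs=1e-3)
        assert se == pytest.approx(0.03844, abs=1e-3)

    def test_constructed_symmetry(self):
        e = math.e
        z = stats.norm.ppf(0.975)
        beta, se = or_ci_to_logscale(e, e * math.exp(-z), e * math.exp(z))
        assert beta == pytest.approx(1.0, rel=1e-12)
        assert se == pytest.approx(1.0, rel=1e-12)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            or_ci_to_logscale(-1.0, 0.5, 2.0)
        with pytest.raises(ValueError):
            or_ci_to_logscale(0.9, 1.0, 1.1)
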