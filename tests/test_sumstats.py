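"""Summary-statistic parsing, QC filtering, harmonization and sign flip."""

import numpy as np
import pandas as pd
import pytest

import pleioscan as ps
from conftest import make_sumstats

HEADER = "rsid\tchrom\tpos\teffect_allele\tother_allele\teaf\tinfo\tbeta\tse\tp\n"


def _write(tmp_path, body, header=HEADER, name="ss.tsv"):
    path = tmp_path / name
    path.write_text(header + body)
    return path


WELL_FORMED = (
    "rs1\t1\t100\tA\tG\t0.3\t0.99\t0.10\t0.02\t5.7e-7\n"
    "rs2\t1\t200\tC\tT\t0.2\t0.95\t-0.05\t0.03\t0.096\n"
    "rs3\t2\t300\tG\tA\t0.45\t0.90\t0.02\t0.01\t0.046\n"
    "rs4\t2\t400\tT\tG\t0.10\t0.85\t0.00\t0.05\t1.0\n"
    "rs5\t3\t500\tA\tC\t0.05\t0.80\t0.30\t0.04\t6.3e-14\n"
)


class TestReadSumstats:
    def test_well_formed_file_is_read_verbatim(self, tmp_path):
        df, report = ps.read_sumstats(_write(tmp_path, WELL_FORMED))
        assert len(df) == 5
        assert report.n_retained == 5 and not report.rejected
        assert df.attrs["sign_flipped"] is False

    def test_zero_se_row_rejected_and_counted(self, tmp_path):
        body = WELL_FORMED + "rs6\t3\t600\tA\tG\t0.3\t0.9\t0.1\t0\t0.5\n"
        df, report = ps.read_sumstats(_write(tmp_path, body))
        assert len(df) == 5
        assert report.rejected["nonpositive_se"] == 1

    def test_indel_and_multiallelic_rows_rejected(self, tmp_path):
        body = WELL_FORMED + "rs7\t3\t700\tAT\tG\t0.3\t0.9\t0.1\t0.02\t0.5\n"
        df, report = ps.read_sumstats(_write(tmp_path, body))
        assert report.rejected["invalid_alleles"] == 1

    def test_column_map_reproduces_canonical_order(self, tmp_path):
        header = "P\tBETA\tSNP\tCHR\tBP\tA1\tA2\tFRQ\tINFO\tSE\n"
        body = "5.7e-7\t0.10\trs1\t1\t100\tA\tG\t0.3\t0.99\t0.02\n"
        cmap = {"rsid": "SNP", "chrom": "CHR", "pos": "BP",
                "effect_allele": "A1", "other_allele": "A2", "eaf": "FRQ",
                "info": "INFO", "beta": "BETA", "se": "SE", "p": "P"}
        df, _ = ps.read_sumstats(_write(tmp_path, body, header=header), column_map=cmap)
        ref, _ = ps.read_sumstats(_write(tmp_path, WELL_FORMED, name="ref.tsv"))
        pd.testing.assert_frame_equal(df, ref.iloc[[0]])

    def test_missing_mandatory_column_raises(self, tmp_path):
        header = "rsid\tchrom\tpos\teffect_allele\tbeta\tse\tp\n"
        with pytest.raises(ps.FormatError, match="other_allele"):
            ps.read_sumstats(_write(tmp_path, "rs1\t1\t100\tA\t0.1\t0.02\t0.5\n",
                                    header=header))

    def test_empty_file_raises(self, tmp_path):
        with pytest.raises(ps.FormatError):
            ps.read_sumstats(_write(tmp_path, "", header=""))

    def test_duplicate_rsid_keeps_smallest_p(self, tmp_path):
        body = ("rs1\t1\t100\tA\tG\t0.3\t0.99\t0.10\t0.02\t0.5\n"
                "rs1\t1\t100\tA\tG\t0.3\t0.99\t0.20\t0.02\t0.001\n")
        df, report = ps.read_sumstats(_write(tmp_path, body))
        assert len(df) == 1 and report.n_duplicates_removed == 1
        assert df.loc[0, "beta"] == 0.20

    def test_missing_p_recomputed_from_beta_and_se(self, tmp_path):
        header = "rsid\tchrom\tpos\teffect_allele\tother_allele\tbeta\tse\n"
        df, _ = ps.read_sumstats(_write(tmp_path, "rs1\t1\t100\tA\tG\t0.1\t0.05\n",
                                        header=header))
        from scipy.stats import norm
        assert df.loc[0, "p"] == pytest.approx(2 * norm.sf(2.0), rel=1e-12)

    def test_chr_prefix_stripped(self, tmp_path):
        body = "rs1\tchr1\t100\tA\tG\t0.3\t0.99\t0.1\t0.02\t0.5\n"
        df, _ = ps.read_sumstats(_write(tmp_path, body))
        assert df.loc[0, "chrom"] == "1"

    def test_roundtrip_preserves_floats_exactly(self, tmp_path, rng):
        df = make_sumstats([{"beta": rng.standard_normal() * 0.1,
                             "se": float(rng.uniform(0.01, 0.05)),
                             "eaf": float(rng.uniform(0.01, 0.5))}
                            for _ in range(20)])
        path = tmp_path / "rt.tsv"
        ps.write_sumstats(df, path)
        back, _ = ps.read_sumstats(path)
        for col in ("beta", "se", "p", "eaf"):
            assert np.array_equal(back[col].to_numpy(), df[col].to_numpy())


class TestQcFilters:
    def test_maf_boundary_is_inclusive(self):
        df = make_sumstats([{"beta": 0.1, "se": 0.02, "eaf": 0.004},
                            {"beta": 0.1, "se": 0.02, "eaf": 0.005},
                            {"beta": 0.1, "se": 0.02, "eaf": 0.996},
                            {"beta": 0.1, "se": 0.02, "eaf": 0.995}])
        out, report = ps.apply_qc_filters(df)
        assert list(out["eaf"]) == [0.005, 0.995]
        assert report.loc[0, "n_removed"] == 2

    def test_info_boundary_and_missing_pass(self):
        df = make_sumstats([{"beta": 0.1, "se": 0.02, "info": 0.29},
                            {"beta": 0.1, "se": 0.02, "info": 0.3},
                            {"beta": 0.1, "se": 0.02, "info": np.nan},
                            {"beta": 0.1, "se": 0.02, "eaf": np.nan}])
        out, _ = ps.apply_qc_filters(df)
        assert len(out) == 3

    def test_clean_records_pass_unchanged(self):
        df = make_sumstats([{"beta": 0.1, "se": 0.02, "eaf": 0.5, "info": 1.0}] * 3)
        out, report = ps.apply_qc_filters(df)
        assert len(out) == 3 and report["n_removed"].sum() == 0

    def test_raising_maf_min_is_monotone(self):
        df = make_sumstats([{"beta": 0.1, "se": 0.02, "eaf": e}
                            for e in np.linspace(0.001, 0.5, 40)])
        kept = [len(ps.apply_qc_filters(df, maf_min=m)[0])
                for m in (0.001, 0.005, 0.01, 0.05, 0.1)]
        assert kept == sorted(kept, reverse=True)


class TestFlipSign:
    def test_autoimmune_betas_negated_rest_untouched(self):
        df = make_sumstats([{"beta": 0.12, "se": 0.02}, {"beta": 0.0, "se": 0.02}])
        out = ps.flip_sign(df, "autoimmune")
        assert out.loc[0, "beta"] == -0.12 and out.loc[1, "beta"] == 0.0
        assert out.loc[0, "se"] == df.loc[0, "se"]
        assert out.loc[0, "p"] == df.loc[0, "p"]
        assert out.attrs["sign_flipped"] is True

    def test_cancer_table_unchanged(self):
        df = make_sumstats([{"beta": 0.12, "se": 0.02}])
        out = ps.flip_sign(df, "cancer")
        assert out.loc[0, "beta"] == 0.12
        assert out.attrs["sign_flipped"] is False

    def test_double_flip_rejected(self):
        df = make_sumstats([{"beta": 0.12, "se": 0.02}])
        once = ps.flip_sign(df, "autoimmune")
        with pytest.raises(ps.StateError):
            ps.flip_sign(once, "autoimmune")


class TestHarmonizePair:
    def test_allele_swap_negates_beta(self):
        a = make_sumstats([{"effect_allele": "A", "other_allele": "G",
                            "beta": 0.1, "se": 0.02, "eaf": 0.3}])
        b = make_sumstats([{"effect_allele": "G", "other_allele": "A",
                            "beta": 0.2, "se": 0.02, "eaf": 0.7}])
        pair = ps.harmonize_pair(a, b)
        row = pair.df.iloc[0]
        assert row["effect_allele"] == "A"
        assert row["beta_b"] == pytest.approx(-0.2)
        assert row["eaf_b"] == pytest.approx(0.3)
        assert bool(row["allele_swapped"]) and not bool(row["strand_flipped"])

    def test_strand_flip_keeps_beta(self):
        a = make_sumstats([{"effect_allele": "A", "other_allele": "G",
                            "beta": 0.1, "se": 0.02}])
        b = make_sumstats([{"effect_allele": "T", "other_allele": "C",
                            "beta": 0.2, "se": 0.02}])
        pair = ps.harmonize_pair(a, b)
        row = pair.df.iloc[0]
        assert row["beta_b"] == pytest.approx(0.2)
        assert bool(row["strand_flipped"]) and not bool(row["allele_swapped"])

    def test_palindromic_mid_frequency_dropped(self):
        a = make_sumstats([{"effect_allele": "A", "other_allele": "T",
                            "beta": 0.1, "se": 0.02, "eaf": 0.5},
                           {"effect_allele": "C", "other_allele": "A",
                            "beta": 0.1, "se": 0.02}])
        b = make_sumstats([{"effect_allele": "A", "other_allele": "T",
                            "beta": 0.2, "se": 0.02, "eaf": 0.5},
                           {"effect_allele": "C", "other_allele": "A",
                            "beta": 0.2, "se": 0.02}])
        pair = ps.harmonize_pair(a, b)
        assert pair.drops == {"palindromic_ambiguous": 1}
        assert list(pair.df["rsid"]) == ["rs2"]

    def test_palindromic_extreme_frequency_resolved_by_eaf(self):
        a = make_sumstats([{"effect_allele": "A", "other_allele": "T",
                            "beta": 0.1, "se": 0.02, "eaf": 0.1}])
        b = make_sumstats([{"effect_allele": "A", "other_allele": "T",
                            "beta": 0.2, "se": 0.02, "eaf": 0.9}])
        pair = ps.harmonize_pair(a, b)
        # discordant frequencies imply the labels refer to opposite strands
        assert pair.df.loc[0, "beta_b"] == pytest.approx(-0.2)

    def test_incompatible_alleles_dropped_with_reason(self):
        a = make_sumstats([{"effect_allele": "A", "other_allele": "G",
                            "beta": 0.1, "se": 0.02},
                           {"effect_allele": "A", "other_allele": "C",
                            "beta": 0.1, "se": 0.02}])
        b = make_sumstats([{"effect_allele": "A", "other_allele": "C",
                            "beta": 0.2, "se": 0.02},
                           {"effect_allele": "A", "other_allele": "C",
                            "beta": 0.2, "se": 0.02}])
        pair = ps.harmonize_pair(a, b)
        assert pair.drops == {"incompatible_alleles": 1}
        assert len(pair.df) == 1

    def test_zero_overlap_raises(self):
        a = make_sumstats([{"beta": 0.1, "se": 0.02}])
        b = make_sumstats([{"beta": 0.2, "se": 0.02}])
        b["rsid"] = ["rsX"]
        with pytest.raises(ps.PipelineError):
            ps.harmonize_pair(a, b)

    def test_involution_same_retained_set_and_magnitudes(self):
        cfg = ps.SimulationConfig(seed=5, n_snps=80, n_blocks=10,
                                  block_rho=0.6, n_individuals=400,
                                  allele_perturb_rate=0.4)
        g, snp_map = ps.simulate_ld_genotypes(cfg)
        a, b = ps.simulate_pair_sumstats(g, snp_map, cfg)
        ab = ps.harmonize_pair(a, b)
        ba = ps.harmonize_pair(b, a)
        assert set(ab.df["rsid"]) == set(ba.df["rsid"])
        left = ab.df.set_index("rsid")
        right = ba.df.set_index("rsid").loc[left.index]
        assert np.allclose(np.abs(left["beta_b"]), np.abs(right["beta_a"]))
        assert np.allclose(np.abs(left["beta_a"]), np.abs(right["beta_b"]))
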