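"""Synthetic-data generators: LD structure, planted effects, calibration."""

import numpy as np
import pandas as pd
import pytest

import pleioscan as ps
from pleioscan.simulate import effective_sample_size


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_snps": 0}, {"n_individuals": -1}, {"block_rho": 1.0},
        {"block_rho": -0.1}, {"maf_range": (0.0, 0.4)},
        {"maf_range": (0.2, 0.6)}, {"infiltration_loading": 1.5},
        {"n_blocks": 1000, "n_snps": 10},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ps.ConfigError):
            ps.SimulationConfig(**kwargs)

    def test_planted_effect_class_invariants(self):
        with pytest.raises(ps.ConfigError):
            ps.PlantedEffect(0, "opposite", 0.1, 0.1)
        with pytest.raises(ps.ConfigError):
            ps.PlantedEffect(0, "concordant", 0.1, -0.1)
        with pytest.raises(ps.ConfigError):
            ps.PlantedEffect(0, "null", 0.1, 0.0)
        with pytest.raises(ps.ConfigError):
            ps.PlantedEffect(0, "mystery", 0.1, 0.1)

    def test_planted_index_out_of_range_rejected(self):
        with pytest.raises(ps.ConfigError):
            ps.SimulationConfig(n_snps=10,
                                planted_effects=[ps.PlantedEffect(10, "null")])


class TestLdGenotypes:
    def test_fixed_seed_is_byte_identical(self, tiny_config):
        g1, m1 = ps.simulate_ld_genotypes(tiny_config)
        g2, m2 = ps.simulate_ld_genotypes(tiny_config)
        assert np.array_equal(g1, g2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_dosages_bounded_and_positions_increasing(self, tiny_config):
        g, snp_map = ps.simulate_ld_genotypes(tiny_config)
        assert g.min() >= 0 and g.max() <= 2
        assert (np.diff(snp_map["pos"]) > 0).all()

    def test_zero_rho_gives_independent_snps(self):
        cfg = ps.SimulationConfig(seed=9, n_snps=30, n_blocks=3, block_rho=0.0,
                                  n_individuals=2000)
        g, _ = ps.simulate_ld_genotypes(cfg)
        r = np.corrcoef(g.T.astype(float))
        off = r[~np.eye(30, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_calibrated_adjacent_correlation_hits_block_rho(self):
        # thresholding-calibration check at large n
        cfg = ps.SimulationConfig(seed=13, n_snps=6, n_blocks=1, block_rho=0.9,
                                  maf_range=(0.25, 0.35), n_individuals=100_000)
        g, _ = ps.simulate_ld_genotypes(cfg)
        r = np.corrcoef(g[:, 0].astype(float), g[:, 1].astype(float))[0, 1]
        assert r ** 2 == pytest.approx(0.81, abs=0.02)

    def test_cross_block_correlation_vanishes(self):
        cfg = ps.SimulationConfig(seed=9, n_snps=20, n_blocks=2, block_rho=0.9,
                                  n_individuals=5000)
        g, snp_map = ps.simulate_ld_genotypes(cfg)
        first = snp_map.index[snp_map["block"] == 0]
        second = snp_map.index[snp_map["block"] == 1]
        r = np.corrcoef(g.T.astype(float))
        assert np.abs(r[np.ix_(first, second)]).max() < 0.1

    def test_empirical_frequencies_match_configured_mafs(self):
        cfg = ps.SimulationConfig(seed=17, n_snps=200, n_blocks=20,
                                  block_rho=0.5, n_individuals=2000)
        g, snp_map = ps.simulate_ld_genotypes(cfg)
        eaf = g.mean(axis=0) / 2
        maf = snp_map["maf"].to_numpy()
        sd = np.sqrt(maf * (1 - maf) / (2 * cfg.n_individuals))
        n_beyond_3sd = int((np.abs(eaf - maf) > 3 * sd).sum())
        assert n_beyond_3sd <= 3          # ~0.5 expected at 200 SNPs
        assert (np.abs(eaf - maf) <= 5 * sd).all()


class TestPairSumstats:
    def test_determinism_and_full_column_contract(self, tiny_config):
        g, snp_map = ps.simulate_ld_genotypes(tiny_config)
        a1, b1 = ps.simulate_pair_sumstats(g, snp_map, tiny_config)
        a2, b2 = ps.simulate_pair_sumstats(g, snp_map, tiny_config)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)
        assert list(a1.columns) == ["rsid", "chrom", "pos", "effect_allele",
                                    "other_allele", "eaf", "info", "beta",
                                    "se", "p"]

    def test_se_matches_analytic_formula_exactly(self, tiny_config):
        g, snp_map = ps.simulate_ld_genotypes(tiny_config)
        a, _ = ps.simulate_pair_sumstats(g, snp_map, tiny_config)
        expect = 1.0 / np.sqrt(2.0 * effective_sample_size(
            tiny_config.n_cases_a, tiny_config.n_controls_a)
            * a["eaf"] * (1 - a["eaf"]))
        assert np.allclose(a["se"], expect, rtol=1e-12, atol=0)

    def test_null_snps_have_nominal_type_one_error(self):
        cfg = ps.SimulationConfig(seed=23, n_snps=2000, n_blocks=200,
                                  block_rho=0.0, n_individuals=400)
        g, snp_map = ps.simulate_ld_genotypes(cfg)
        a, b = ps.simulate_pair_sumstats(g, snp_map, cfg)
        for df in (a, b):
            rate = (df["p"] < 0.05).mean()
            assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / 2000))

    def test_opposite_effects_powered_at_per_trait_threshold(self):
        # beta 0.15 at 50k/50k: analytic power at alpha=1e-3 is ~1
        cfg = ps.SimulationConfig(seed=29, n_snps=100, n_blocks=50,
                                  block_rho=0.9, n_individuals=1000)
        cfg.planted_effects = ps.plant_effects(cfg, n_opposite=50, beta=0.15)
        g, snp_map = ps.simulate_ld_genotypes(cfg)
        a, b = ps.simulate_pair_sumstats(g, snp_map, cfg)
        causal = [snp_map.loc[e.snp_index, "rsid"] for e in cfg.planted_effects]
        pa = a.set_index("rsid").loc[causal, "p"]
        pb = b.set_index("rsid").loc[causal, "p"]
        frac = ((pa < 1e-3) & (pb < 1e-3)).mean()
        assert frac > 0.95

    def test_planted_effect_on_monomorphic_snp_rejected(self, tiny_config):
        g, snp_map = ps.simulate_ld_genotypes(tiny_config)
        g = g.copy()
        g[:, 4] = 0
        cfg = ps.SimulationConfig(
            **{**tiny_config.__dict__,
               "planted_effects": [ps.PlantedEffect(4, "a_only", beta_a=0.2)]})
        with pytest.raises(ps.PipelineError, match="monomorphic"):
            ps.simulate_pair_sumstats(g, snp_map, cfg)

    def test_allele_perturbation_keeps_association_after_harmonization(self):
        cfg = ps.SimulationConfig(seed=31, n_snps=60, n_blocks=10,
                                  block_rho=0.6, n_individuals=500,
                                  allele_perturb_rate=0.5)
        g, snp_map = ps.simulate_ld_genotypes(cfg)
        a, b = ps.simulate_pair_sumstats(g, snp_map, cfg)
        assert (a["effect_allele"] != b["effect_allele"]).any()
        pair = ps.harmonize_pair(a, b)
        assert len(pair.df) == len(a)  # non-palindromic pairs all resolve
        assert (pair.df["allele_swapped"] | pair.df["strand_flipped"]).any()

    def test_phenotype_mode_recovers_a_strong_effect(self):
        cfg = ps.SimulationConfig(seed=37, n_snps=12, n_blocks=4,
                                  block_rho=0.5, n_individuals=200,
                                  n_cases_a=1500, n_controls_a=1500,
                                  n_cases_b=1500, n_controls_b=1500)
        cfg.planted_effects = [ps.PlantedEffect(1, "opposite", 0.6, -0.6)]
        g, snp_map = ps.simulate_ld_genotypes(cfg)
        a, b = ps.simulate_pair_sumstats(g, snp_map, cfg, mode="phenotype")
        assert a.loc[1, "beta"] > 0.3 and a.loc[1, "p"] < 1e-4
        assert b.loc[1, "beta"] < -0.3
        assert (a["se"] > 0).all()


class TestExpression:
    def test_rows_are_z_scored(self, tiny_config):
        cohorts = ps.simulate_expression(tiny_config, ["GENE0001"],
                                         ["CD4", "CD8A", "ITGAM", "PTPRC"])
        for df in cohorts.values():
            x = df.to_numpy()
            assert np.abs(x.mean(axis=1)).max() < 1e-9
            assert np.abs(x.std(axis=1) - 1).max() < 1e-9

    def test_determinism(self, tiny_config):
        c1 = ps.simulate_expression(tiny_config, ["GENE0001"], ["CD4"])
        c2 = ps.simulate_expression(tiny_config, ["GENE0001"], ["CD4"])
        for k in c1:
            pd.testing.assert_frame_equal(c1[k], c2[k])

    def test_bad_loading_rejected(self, tiny_config):
        cfg = ps.SimulationConfig(**{**tiny_config.__dict__,
                                     "infiltration_loading": 0.5})
        object.__setattr__(cfg, "infiltration_loading", 1.5)
        with pytest.raises(ps.ConfigError):
            ps.simulate_expression(cfg, ["GENE0001"], ["CD4"])

    def test_driven_gene_outside_universe_rejected(self, tiny_config):
        with pytest.raises(ps.ConfigError):
            ps.simulate_expression(tiny_config, ["NOT_A_GENE"], ["CD4"],
                                   gene_universe=["CD4", "GENE0001"])


class TestGeneAnnotationAndSets:
    def test_gene_intervals_valid_and_deterministic(self, tiny_config):
        g1 = ps.simulate_gene_annotation(tiny_config)
        g2 = ps.simulate_gene_annotation(tiny_config)
        pd.testing.assert_frame_equal(g1, g2)
        assert (g1["start"] <= g1["end"]).all()
        assert len(g1) == tiny_config.n_genes

    def test_gene_sets_partition_immune_and_background(self):
        symbols = [f"GENE{i:04d}" for i in range(100)]
        immune, pathways = ps.simulate_gene_sets(symbols, symbols[:10], seed=3)
        assert immune.members == frozenset(symbols[:10])
        names = [p.name for p in pathways]
        assert any("cytokine" in n for n in names)
        assert any("metabolic" in n for n in names)
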