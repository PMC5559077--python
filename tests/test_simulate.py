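"""Synthetic-data generator: LD structure, effects, outcomes, exclusions."""

import numpy as np
import pytest

from herra import (SimulationConfig, apply_scenario_exclusions,
                   draw_causal_effects, read_plink, simulate_dataset,
                   simulate_genotypes, simulate_phenotype, write_plink)
from herra.genotype_io import standardize


def _adjacent_r2(g, n_pairs=200):
    x = standardize(g).matrix
    r = np.array([np.corrcoef(x[:, j], x[:, j + 1])[0, 1]
                  for j in range(min(n_pairs, g.n_snps - 1))])
    return np.mean(r**2)


class TestGenotypes:
    def test_zero_ld_gives_independent_adjacent_snps(self):
        cfg = SimulationConfig(n_samples=5000, n_snps=120, ld_decay=0.0,
                               n_causal=1, seed=10)
        g, _ = simulate_genotypes(cfg)
        x = standardize(g).matrix
        r = np.array([np.corrcoef(x[:, j], x[:, j + 1])[0, 1]
                      for j in range(119)])
        assert np.abs(r).mean() < 0.05

    def test_high_ld_gives_strong_adjacent_correlation(self):
        cfg = SimulationConfig(n_samples=5000, n_snps=120, ld_decay=0.9,
                               n_causal=1, seed=11)
        g, _ = simulate_genotypes(cfg)
        assert _adjacent_r2(g) > 0.5

    def test_ld_monotone_in_decay_parameter(self):
        vals = []
        for ld in (0.0, 0.5, 0.9):
            cfg = SimulationConfig(n_samples=3000, n_snps=100, ld_decay=ld,
                                   n_causal=1, seed=12)
            vals.append(_adjacent_r2(simulate_genotypes(cfg)[0]))
        assert vals[0] < vals[1] < vals[2]

    def test_empirical_maf_within_requested_range(self):
        cfg = SimulationConfig(n_samples=5000, n_snps=300,
                               maf_range=(0.1, 0.4), n_causal=1, seed=13)
        g, _ = simulate_genotypes(cfg)
        assert g.maf.min() > 0.1 - 0.03
        assert g.maf.max() < 0.4 + 0.03

    def test_genotypes_are_allele_counts(self):
        g, pool = simulate_genotypes(SimulationConfig(n_samples=50, n_snps=20,
                                                      n_causal=1, seed=14))
        assert np.isin(g.genotypes, (0.0, 1.0, 2.0)).all()
        assert set(np.unique(pool)) <= {0, 1}

    def test_chromosome_blocks_partition_snps(self):
        cfg = SimulationConfig(n_samples=40, n_snps=100, n_chromosomes=5,
                               n_causal=1, seed=15)
        g, _ = simulate_genotypes(cfg)
        labels, counts = np.unique(g.snp_chrom, return_counts=True)
        assert len(labels) == 5
        assert counts.sum() == g.n_snps


class TestCausalEffects:
    @pytest.mark.parametrize("h2,expected", [(0.1, 1 / 9), (0.6, 1.5)])
    def test_genetic_variance_from_h2(self, h2, expected):
        cfg = SimulationConfig(n_samples=200, n_snps=100, n_causal=20,
                               h2_true=h2, seed=16, exact_normalization=True)
        g, _ = simulate_genotypes(cfg)
        truth = draw_causal_effects(cfg, g)
        assert cfg.sigma_g2 == pytest.approx(expected, rel=1e-9)
        assert np.sum(truth.effects**2) == pytest.approx(expected, rel=1e-12)

    def test_random_effects_match_variance_in_expectation(self):
        cfg = SimulationConfig(n_samples=100, n_snps=400, n_causal=200,
                               h2_true=0.3, seed=17)
        g, _ = simulate_genotypes(cfg)
        truth = draw_causal_effects(cfg, g)
        # 200 draws: realized sum of squares within 30% of target
        assert truth.sigma_g2 == pytest.approx(cfg.sigma_g2, rel=0.3)

    def test_maf_restricted_causals(self):
        cfg = SimulationConfig(n_samples=2000, n_snps=300, n_causal=10,
                               h2_true=0.3, scenario="maf_restricted",
                               causal_maf_max=0.1, maf_range=(0.02, 0.5),
                               seed=18)
        g, _ = simulate_genotypes(cfg)
        truth = draw_causal_effects(cfg, g)
        assert np.all(g.maf[truth.causal_indices] <= 0.1)

    def test_insufficient_low_maf_snps_rejected(self):
        cfg = SimulationConfig(n_samples=500, n_snps=50, n_causal=40,
                               h2_true=0.3, scenario="maf_restricted",
                               causal_maf_max=0.06, maf_range=(0.2, 0.5),
                               seed=19)
        g, _ = simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="0.06"):
            draw_causal_effects(cfg, g)


class TestPhenotypes:
    def test_continuous_outcome_variance(self):
        # h2=0.1, sigma_e2=1: total variance 1/0.9
        cfg = SimulationConfig(n_samples=20000, n_snps=120, n_causal=30,
                               h2_true=0.1, seed=20, exact_normalization=True)
        g, ph, _ = simulate_dataset(cfg)
        assert np.var(ph.y, ddof=1) == pytest.approx(1 / 0.9, abs=0.05)

    def test_balanced_binary_threshold(self):
        cfg = SimulationConfig(n_samples=10000, n_snps=100, n_causal=20,
                               h2_true=0.3, outcome="binary", binary_K=0.5,
                               seed=21)
        _, ph, _ = simulate_dataset(cfg)
        assert abs(ph.y.mean() - 0.5) < 0.02

    def test_unbalanced_binary_prevalence(self):
        cfg = SimulationConfig(n_samples=20000, n_snps=100, n_causal=20,
                               h2_true=0.3, outcome="binary", binary_K=0.2,
                               seed=22, exact_normalization=True)
        _, ph, _ = simulate_dataset(cfg)
        assert abs(ph.y.mean() - 0.2) < 0.02

    def test_censoring_rate_near_half(self):
        cfg = SimulationConfig(n_samples=10000, n_snps=100, n_causal=20,
                               h2_true=0.1, outcome="survival", censor_sd=2.0,
                               seed=23)
        _, ph, _ = simulate_dataset(cfg)
        assert abs((1 - ph.event.mean()) - 0.5) < 0.04


class TestScenarioExclusions:
    def _one_causal_at(self, idx, m=40, flank=5):
        cfg = SimulationConfig(n_samples=60, n_snps=m, n_causal=1,
                               h2_true=0.3, scenario="untyped_causal",
                               flank_exclusion=flank, seed=24)
        g, _ = simulate_genotypes(cfg)
        truth = draw_causal_effects(cfg, g)
        truth.causal_indices = np.array([idx])
        return apply_scenario_exclusions(g, truth, cfg)

    def test_interior_causal_removes_causal_plus_flanks(self):
        g_obs, truth = self._one_causal_at(10)
        assert g_obs.n_snps == 40 - 11  # 1 + 2*5
        removed = set(range(40)) - set(truth.observed_snp_indices)
        assert removed == set(range(5, 16))

    def test_edge_causal_clips_window(self):
        g_obs, _ = self._one_causal_at(2)
        assert g_obs.n_snps == 40 - 8  # indices 0..7

    def test_typed_scenario_is_identity(self):
        cfg = SimulationConfig(n_samples=60, n_snps=30, n_causal=3,
                               h2_true=0.3, scenario="typed", seed=25)
        g, _ = simulate_genotypes(cfg)
        truth = draw_causal_effects(cfg, g)
        g_obs, truth = apply_scenario_exclusions(g, truth, cfg)
        assert g_obs.n_snps == 30
        np.testing.assert_array_equal(truth.observed_snp_indices,
                                      np.arange(30))

    def test_exclusion_respects_chromosome_boundaries(self):
        cfg = SimulationConfig(n_samples=60, n_snps=40, n_chromosomes=2,
                               n_causal=1, h2_true=0.3,
                               scenario="untyped_causal", flank_exclusion=5,
                               seed=26)
        g, _ = simulate_genotypes(cfg)
        truth = draw_causal_effects(cfg, g)
        truth.causal_indices = np.array([18])  # 2 from the chrom-1 end
        g_obs, _ = apply_scenario_exclusions(g, truth, cfg)
        # window 13..23 clipped at the chromosome boundary (20): only 13..19
        assert g_obs.n_snps == 40 - 7


def test_simulated_dataset_round_trips_through_plink(tmp_path):
    cfg = SimulationConfig(n_samples=30, n_snps=25, n_causal=5, h2_true=0.3,
                           seed=27)
    g, _, _ = simulate_dataset(cfg)
    write_plink(g, tmp_path / "sim")
    back = read_plink(tmp_path / "sim")
    np.testing.assert_array_equal(back.genotypes, g.genotypes)
    assert list(back.snp_chrom) == list(g.snp_chrom)


def test_phenotype_dispatch_unknown_outcome_rejected():
    cfg = SimulationConfig(n_samples=50, n_snps=20, n_causal=2, h2_true=0.3,
                           seed=28)
    g, _ = simulate_genotypes(cfg)
    truth = draw_causal_effects(cfg, g)
    cfg.outcome = "ordinal"
    with pytest.raises(ValueError):
        simulate_phenotype(g, truth, cfg)
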