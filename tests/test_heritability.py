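"""Heritability assembly: variances, liability transform, covariates."""

import numpy as np
import pytest
from scipy.stats import norm

from herra import (RCVConfig, SimulationConfig, binary_outcome_variance,
                   covariate_adjusted_heritability, empirical_outcome_variance,
                   estimate_heritability, heritability_observed,
                   liability_transform, simulate_dataset)
from herra.genotype_io import PhenotypeSet


class TestVariances:
    def test_sample_variance(self):
        assert empirical_outcome_variance([1, 2, 3, 4]) == pytest.approx(5 / 3)
        assert empirical_outcome_variance(np.full(5, 2.0)) == 0.0
        with pytest.raises(ValueError):
            empirical_outcome_variance([1.0])

    def test_binary_variance(self):
        d = np.repeat([0.0, 1.0], 50)
        assert binary_outcome_variance(d) == pytest.approx(0.25)
        # case/control counts of the colorectal-cancer analysis
        d = np.r_[np.ones(4312), np.zeros(4356)]
        assert binary_outcome_variance(d) == pytest.approx(
            4312 * 4356 / 8668**2)
        with pytest.raises(ValueError):
            binary_outcome_variance(np.ones(10))

    def test_observed_scale_identity(self):
        assert heritability_observed(1.0, 1.0 / 0.9) == pytest.approx(0.1,
                                                                      abs=1e-6)
        assert heritability_observed(1.0, 1.0) == 0.0
        assert heritability_observed(1.05, 1.0) == pytest.approx(-0.05)
        with pytest.raises(ValueError):
            heritability_observed(1.0, 0.0)


class TestLiabilityTransform:
    def test_case_control_worked_example(self):
        # observed-scale 0.244 at prevalence 0.004 with 4312/8668 cases
        h2l = liability_transform(0.244, K=0.004, P=4312 / 8668)
        assert round(h2l, 3) == 0.110

    def test_zero_maps_to_zero(self):
        assert liability_transform(0.0, 0.2, 0.5) == 0.0
        assert liability_transform(0.0, 0.01) == 0.0

    def test_balanced_closed_form(self):
        # K = 1/2: z = phi(0), so the factor is 0.25 * 2 * pi
        assert liability_transform(0.1, 0.5) == pytest.approx(
            0.1 * 0.25 * 2 * np.pi / 1.0**0)
        assert liability_transform(0.1, 0.5) == pytest.approx(0.15708, abs=1e-5)

    def test_ascertainment_reduces_to_plain_at_p_equal_k(self):
        for k in (0.05, 0.3, 0.5):
            assert liability_transform(0.2, k, P=k) == pytest.approx(
                liability_transform(0.2, k))

    def test_monotone_in_observed_scale(self):
        vals = [liability_transform(h, 0.1, 0.4) for h in (0.0, 0.1, 0.2, 0.4)]
        assert np.all(np.diff(vals) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            liability_transform(0.2, 0.0)
        with pytest.raises(ValueError):
            liability_transform(0.2, 0.1, P=1.0)


class TestCovariateAdjustment:
    def test_arithmetic_example(self):
        assert covariate_adjusted_heritability(
            0.8, [1.0], [[0.2]], 1.25) == pytest.approx(0.2)

    def test_zero_beta_reduces_to_observed(self):
        assert covariate_adjusted_heritability(
            0.7, np.zeros(3), np.eye(3), 1.4) == pytest.approx(
            heritability_observed(0.7, 1.4))

    def test_psd_covariance_never_increases_h2(self, rng):
        a = rng.normal(size=(4, 4))
        cov = a @ a.T  # PSD
        beta = rng.normal(size=4)
        adj = covariate_adjusted_heritability(0.5, beta, cov, 1.0)
        assert adj <= heritability_observed(0.5, 1.0) + 1e-12

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            covariate_adjusted_heritability(0.5, np.ones(2), np.eye(3), 1.0)


class TestEstimatePipeline:
    def test_continuous_recovery_single_run(self):
        cfg = SimulationConfig(n_samples=1500, n_snps=400, n_causal=10,
                               h2_true=0.4, seed=8100,
                               exact_normalization=True)
        g, ph, _ = simulate_dataset(cfg)
        res = estimate_heritability(g, ph, rcv_cfg=RCVConfig(split_seed=1))
        assert abs(res.h2_observed - 0.4) < 0.15
        assert res.outcome_type == "continuous"

    def test_scale_invariance_of_continuous_estimate(self):
        cfg = SimulationConfig(n_samples=600, n_snps=200, n_causal=10,
                               h2_true=0.3, seed=8200)
        g, ph, _ = simulate_dataset(cfg)
        res = estimate_heritability(g, ph, rcv_cfg=RCVConfig(split_seed=2))
        scaled = PhenotypeSet("continuous", 7.3 * ph.y, sample_id=ph.sample_id)
        res_s = estimate_heritability(g, scaled, rcv_cfg=RCVConfig(split_seed=2))
        assert res_s.h2_observed == pytest.approx(res.h2_observed, rel=1e-8)

    def test_binary_liability_branches_coincide_at_sample_prevalence(self):
        cfg = SimulationConfig(n_samples=1500, n_snps=300, n_causal=10,
                               h2_true=0.4, outcome="binary", binary_K=0.5,
                               seed=8300)
        g, ph, _ = simulate_dataset(cfg)
        p_sample = float(ph.y.mean())
        res = estimate_heritability(g, ph, rcv_cfg=RCVConfig(split_seed=3),
                                    prevalence=p_sample)
        assert res.prevalence_sample == pytest.approx(p_sample)
        assert res.h2_liability == pytest.approx(
            liability_transform(res.h2_observed, p_sample), rel=1e-12)
        assert res.z == pytest.approx(norm.pdf(norm.ppf(1 - p_sample)))

    def test_out_of_range_estimate_flagged_not_clipped(self, rng):
        # pure-noise outcome: h2 near 0, occasionally negative; rerun seeds
        # until one lands negative to check the warning contract
        cfg = SimulationConfig(n_samples=300, n_snps=100, n_causal=5,
                               h2_true=0.01, seed=8400)
        g, _, _ = simulate_dataset(cfg)
        for s in range(12):
            y = rng.normal(size=300)
            ph = PhenotypeSet("continuous", y)
            res = estimate_heritability(g, ph, rcv_cfg=RCVConfig(split_seed=s))
            if res.h2_observed < 0:
                assert res.warnings
                break
        else:
            pytest.skip("no negative draw in 12 noise replicates")

    def test_covariate_adjustment_removes_confounding(self, rng):
        # a strong known covariate: adjusted h2 should track the genetic
        # signal, not the covariate variance
        cfg = SimulationConfig(n_samples=1500, n_snps=300, n_causal=10,
                               h2_true=0.3, seed=8500,
                               exact_normalization=True)
        g, ph, _ = simulate_dataset(cfg)
        w = rng.normal(size=(1500, 1))
        y = ph.y + 1.5 * w[:, 0]
        ph_cov = PhenotypeSet("continuous", y, covariates=w,
                              covariate_names=["env"])
        res = estimate_heritability(g, ph_cov, rcv_cfg=RCVConfig(split_seed=4))
        # the refit absorbs the covariate: residual variance is sigma_e2 = 1,
        # not sigma_e2 + beta^2 var(W) = 3.25
        assert res.sigma_e == pytest.approx(1.0, abs=0.15)
        # the reported h2 is genetic variance over the full phenotypic
        # variance including the covariate term
        sigma_g2 = 0.3 / 0.7
        expected = sigma_g2 / (sigma_g2 + 1.0 + 1.5**2 * np.var(w[:, 0]))
        assert res.h2_observed == pytest.approx(expected, abs=0.06)
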