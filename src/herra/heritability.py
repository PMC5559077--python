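"""Assembling the residual- and total-variance estimates into h2.

The estimator is the identity h2 = 1 - sigma2_e / sigma2_Y: the residual
(environmental) variance comes from the refitted cross-validation scheme
and the total variance from a simple empirical estimator appropriate to
the outcome —

* continuous: the unbiased sample variance of Y;
* dichotomous: Dbar(1 - Dbar) for the 0/1 trait, with the observed-scale
  estimate mapped to the liability scale by the Robertson transform,
  K(1-K)/z^2 without ascertainment or K^2(1-K)^2 / {P(1-P) z^2} when cases
  are oversampled (population prevalence K, sample case fraction P, and z
  the standard-normal density at the threshold truncating the upper K
  tail);
* age-at-onset: the IPCW-weighted variance of the log failure time.

Estimates are reported unclipped; values outside [0, 1] set a warning
flag rather than being truncated, since the estimator's bias behaviour is
the quantity of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .genotype_io import GenotypeDataset, PhenotypeSet, standardize
from .rcv import RCVConfig, SigmaEstimate, rcv_sigma_e, refit_residual_variance
from .screening import (ScreeningConfig, SelectedSet, default_screening_config,
                        screen)
from .survival import ipcw_weights, weighted_outcome_variance

logger = logging.getLogger("herra")


@dataclass
class HeritabilityResult:
    """Heritability estimate with all intermediates of the pipeline."""

    h2_observed: float
    sigma_e: float
    sigma_total: float
    outcome_type: str
    h2_liability: float | None = None
    prevalence_pop: float | None = None
    prevalence_sample: float | None = None
    z: float | None = None
    se: float | None = None
    se_liability: float | None = None
    warnings: list[str] = field(default_factory=list)
    sigma_estimate: SigmaEstimate | None = None
    selected: SelectedSet | None = None
    screen_config: ScreeningConfig | None = None
    rcv_config: RCVConfig | None = None

    def to_dict(self) -> dict:
        out = {
            "h2_observed": self.h2_observed,
            "h2_liability": self.h2_liability,
            "sigma_e": self.sigma_e,
            "sigma_total": self.sigma_total,
            "outcome_type": self.outcome_type,
            "K": self.prevalence_pop,
            "P": self.prevalence_sample,
            "z": self.z,
            "se": self.se,
            "se_liability": self.se_liability,
            "warnings": list(self.warnings),
        }
        if self.sigma_estimate is not None:
            out["sigma_e_split1"] = self.sigma_estimate.sigma_e_split1
            out["sigma_e_split2"] = self.sigma_estimate.sigma_e_split2
            out["support_sizes"] = [len(self.sigma_estimate.support1),
                                    len(self.sigma_estimate.support2)]
            out["penalties"] = [self.sigma_estimate.penalty1,
                                self.sigma_estimate.penalty2]
        if self.selected is not None:
            out["n_screened"] = len(self.selected)
        return out


def empirical_outcome_variance(y: np.ndarray) -> float:
    """Unbiased sample variance sum (Y_i - Ybar)^2 / (N - 1)."""
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    return float(np.var(y, ddof=1))


def binary_outcome_variance(d: np.ndarray) -> float:
    """Dbar(1 - Dbar) for a 0/1 trait."""
    d = np.asarray(d, dtype=float)
    if not np.isin(d, (0.0, 1.0)).all():
        raise ValueError("binary outcome must be coded 0/1")
    dbar = d.mean()
    if dbar in (0.0, 1.0):
        raise ValueError("degenerate binary outcome (all 0s or all 1s)")
    return float(dbar * (1.0 - dbar))


def heritability_observed(sigma_e: float, sigma_total: float) -> float:
    """h2 = 1 - sigma_e / sigma_total, unclipped."""
    if sigma_total <= 0:
        raise ValueError("total variance must be positive")
    return 1.0 - sigma_e / sigma_total


def liability_transform(h2_observed: float, K: float,
                        P: float | None = None) -> float:
    """Robertson transform from the observed 0/1 scale to liability scale.

    Without ascertainment: h2_o * K(1-K) / z^2.  With case-control
    oversampling (sample case fraction P): h2_o * K^2 (1-K)^2 /
    {P(1-P) z^2}.  The two coincide at P = K.
    """
    if not 0.0 < K < 1.0:
        raise ValueError("population prevalence K must be in (0, 1)")
    z = norm.pdf(norm.ppf(1.0 - K))
    if P is None:
        return h2_observed * K * (1.0 - K) / z**2
    if not 0.0 < P < 1.0:
        raise ValueError("sample prevalence P must be in (0, 1)")
    return h2_observed * K**2 * (1.0 - K) ** 2 / (P * (1.0 - P) * z**2)


def covariate_adjusted_heritability(sigma_e: float, beta: np.ndarray,
                                    cov_w: np.ndarray,
                                    sigma_total: float) -> float:
    """1 - {sigma_e + beta' var(W) beta} / sigma_total."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    cov_w = np.atleast_2d(np.asarray(cov_w, dtype=float))
    if cov_w.shape != (len(beta), len(beta)):
        raise ValueError(f"covariance shape {cov_w.shape} does not match "
                         f"{len(beta)} coefficients")
    return 1.0 - (sigma_e + float(beta @ cov_w @ beta)) / sigma_total


def _residualize(y: np.ndarray, w_mat: np.ndarray,
                 weights: np.ndarray | None) -> np.ndarray:
    """Residual of y on [1, W] by (weighted) least squares — used to keep
    covariates out of the screening and selection stages."""
    n = len(y)
    z = np.column_stack([np.ones(n), w_mat])
    sw = np.ones(n) if weights is None else np.sqrt(np.asarray(weights, float))
    beta, *_ = np.linalg.lstsq(z * sw[:, None], y * sw, rcond=None)
    return y - z @ beta + float(beta[0])  # keep the location; drop W effects


def estimate_heritability(g: GenotypeDataset, ph: PhenotypeSet,
                          screen_cfg: ScreeningConfig | None = None,
                          rcv_cfg: RCVConfig | None = None,
                          prevalence: float | None = None,
                          sample_prevalence: float | None = None
                          ) -> HeritabilityResult:
    """Run the full pipeline: standardize, screen, refitted cross-validation,
    outcome variance, heritability (with liability transform for binary
    outcomes when a population prevalence is supplied).

    Covariates, when present, are exempt from screening and selection: the
    screening/lasso stages see the outcome residualized on W, while each
    refit includes W alongside the selected SNPs, and the covariate
    variance component beta' var(W) beta is removed from the numerator.
    """
    if len(ph.y) != g.n_samples:
        raise ValueError("phenotype and genotype sample counts differ")
    if screen_cfg is None:
        screen_cfg = default_screening_config(g.n_snps)
    if rcv_cfg is None:
        rcv_cfg = RCVConfig(penalty_rule="min")

    x = standardize(g)
    y = ph.y
    warnings: list[str] = []

    weights = None
    ipcw = None
    if ph.outcome_type == "survival":
        ipcw = ipcw_weights(y, ph.event)
        weights = ipcw.weights

    y_screen = y
    if ph.covariates is not None:
        y_screen = _residualize(y, ph.covariates, weights)

    selected = screen(x, y_screen, g.snp_chrom, screen_cfg, weights)
    logger.info("screening (%s): retained %d of %d SNPs",
                selected.method, len(selected), g.n_snps)
    x_sel = x.matrix[:, selected.snp_indices]

    if ph.covariates is None:
        sigma_est = rcv_sigma_e(x_sel, y, rcv_cfg, weights)
        sigma_e = sigma_est.sigma_e
        cov_term = 0.0
    else:
        sigma_est, cov_term = _rcv_with_covariates(
            x_sel, y, y_screen, ph.covariates, rcv_cfg, weights)
        sigma_e = sigma_est.sigma_e

    if ph.outcome_type == "continuous":
        sigma_total = empirical_outcome_variance(y)
    elif ph.outcome_type == "binary":
        sigma_total = binary_outcome_variance(y)
    else:
        sigma_total = weighted_outcome_variance(ipcw, y)

    h2 = 1.0 - (sigma_e + cov_term) / sigma_total
    if not 0.0 <= h2 <= 1.0:
        warnings.append(f"h2_observed = {h2:.4f} outside [0, 1]")

    result = HeritabilityResult(
        h2_observed=h2, sigma_e=sigma_e, sigma_total=sigma_total,
        outcome_type=ph.outcome_type, warnings=warnings,
        sigma_estimate=sigma_est, selected=selected,
        screen_config=screen_cfg, rcv_config=rcv_cfg,
    )
    if ph.outcome_type == "binary" and prevalence is not None:
        P = sample_prevalence if sample_prevalence is not None else float(y.mean())
        result.prevalence_pop = prevalence
        result.prevalence_sample = P
        result.z = float(norm.pdf(norm.ppf(1.0 - prevalence)))
        result.h2_liability = liability_transform(h2, prevalence, P)
    return result


def _rcv_with_covariates(x_sel: np.ndarray, y: np.ndarray,
                         y_resid: np.ndarray, w_mat: np.ndarray,
                         rcv_cfg: RCVConfig,
                         weights: np.ndarray | None
                         ) -> tuple[SigmaEstimate, float]:
    """RCV where the lasso selects on the covariate-residualized outcome and
    each opposite-half refit regresses the raw outcome on
    [SNP support, covariates] jointly.

    Returns the sigma estimate plus the averaged beta' var(W) beta term.
    """
    from .rcv import _effective_config, lasso_select, split_sample

    q = w_mat.shape[1]
    a_idx, b_idx = split_sample(len(y), rcv_cfg.split_seed)
    wa = weights[a_idx] if weights is not None else None
    wb = weights[b_idx] if weights is not None else None
    eff = _effective_config(rcv_cfg, n_half=min(len(a_idx), len(b_idx)) - q)

    cov_w = np.cov(w_mat, rowvar=False, ddof=1).reshape(q, q)
    halves = []
    for sel_idx, sel_w, fit_idx, fit_w, off in (
            (a_idx, wa, b_idx, wb, 1), (b_idx, wb, a_idx, wa, 2)):
        sup, pen = lasso_select(x_sel[sel_idx], y_resid[sel_idx], eff, sel_w,
                                fold_seed=rcv_cfg.split_seed + off)
        design = np.column_stack([x_sel[fit_idx][:, sup], w_mat[fit_idx]])
        refit = refit_residual_variance(design, y[fit_idx],
                                        np.arange(len(sup) + q), fit_w)
        beta_w = refit.coefs[len(sup):]
        halves.append((sup, pen, refit, float(beta_w @ cov_w @ beta_w)))

    (sup1, pen1, refit1, c1), (sup2, pen2, refit2, c2) = halves
    est = SigmaEstimate(
        sigma_e_split1=refit1.sigma2, sigma_e_split2=refit2.sigma2,
        sigma_e=(refit1.sigma2 + refit2.sigma2) / 2.0,
        support1=sup1, support2=sup2, refit1=refit1, refit2=refit2,
        penalty1=pen1, penalty2=pen2)
    return est, (c1 + c2) / 2.0
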