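"""Weighted-bootstrap standard errors for the heritability estimate.

Each replicate perturbs the observations with i.i.d. positive mean-1,
variance-1 weights (standard exponential — a Bayesian-bootstrap-style
scheme) and re-runs Steps 2-4 of the estimation.  The screening step is
fixed at its original (unweighted) selection: because the residual-variance
estimator enjoys the oracle property with respect to the screened set,
screening need not be perturbed, which is also the dominant cost saving.

The lasso penalty is fixed across replicates at a calibrated value: the
average, over a first batch of weighted datasets, of the one-SE-rule
penalty (the most regularized model within one standard error of the CV
minimum).  Weight noise inflates the apparent signal heterogeneity, so
this calibrated penalty sits above the unweighted choice on average; a
second, independent batch of weighted datasets then yields the SE with
the penalty held at that value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .genotype_io import PhenotypeSet
from .rcv import RCVConfig, choose_penalty, rcv_sigma_e, split_sample
from .survival import ipcw_weights

logger = logging.getLogger("herra")


@dataclass
class BootstrapConfig:
    """Weighted-bootstrap settings (calibration and SE batches)."""

    n_calibration: int = 100
    n_replicates: int = 100
    weight_law: str = "exponential"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.weight_law != "exponential":
            raise ValueError("only the standard-exponential weight law is "
                             "implemented")


@dataclass
class BootstrapResult:
    """SE of the heritability estimate with the per-replicate estimates."""

    se: float
    estimates: np.ndarray
    se_liability: float | None = None
    estimates_liability: np.ndarray | None = None
    penalty: float | None = None


def draw_bootstrap_weights(n: int, seed: int, spread: float = 1.0) -> np.ndarray:
    """i.i.d. mean-1 weights, 1 + spread * (Exp(1) - 1).

    spread=1 gives the standard-exponential law (variance 1); spread=0
    degenerates to all-ones (used to verify that the bootstrap noise is the
    only source of replicate variability).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    e = np.random.default_rng(seed).standard_exponential(n)
    return 1.0 + spread * (e - 1.0)


def calibrate_penalty(x_screened: np.ndarray, ph: PhenotypeSet,
                      rcv_cfg: RCVConfig, boot_cfg: BootstrapConfig,
                      spread: float = 1.0) -> float:
    """Average one-SE-rule penalty over n_calibration weighted datasets.

    Each calibration replicate reproduces the Step-2 context: the one-SE CV
    penalty is computed on the first half of the (fixed) sample split,
    with the bootstrap weights multiplied into the base (IPCW) weights.
    """
    n = len(ph.y)
    base = _base_weights(ph)
    a_idx, _ = split_sample(n, rcv_cfg.split_seed)
    cfg = replace(rcv_cfg, penalty_rule="one_se", fixed_penalty=None)
    penalties = np.empty(boot_cfg.n_calibration)
    for r in range(boot_cfg.n_calibration):
        omega = draw_bootstrap_weights(n, _sub_seed(boot_cfg.seed, r), spread)
        w = omega if base is None else omega * base
        alpha, _ = choose_penalty(x_screened[a_idx], ph.y[a_idx], cfg,
                                  w[a_idx], fold_seed=rcv_cfg.split_seed + 1)
        penalties[r] = alpha
    lam = float(penalties.mean())
    logger.info("bootstrap calibration: mean one-SE penalty %.4g over %d "
                "weighted datasets", lam, boot_cfg.n_calibration)
    return lam


def weighted_bootstrap_se(x_screened: np.ndarray, ph: PhenotypeSet,
                          penalty: float, rcv_cfg: RCVConfig,
                          boot_cfg: BootstrapConfig,
                          prevalence: float | None = None,
                          spread: float = 1.0) -> BootstrapResult:
    """SE of h2 across n_replicates weighted re-estimations (Steps 2-4 only,
    penalty and sample split held fixed).

    For binary outcomes with a population prevalence, the liability-scale
    SE is computed alongside the observed-scale one.
    """
    n = len(ph.y)
    cfg = replace(rcv_cfg, fixed_penalty=penalty)
    liab = (ph.outcome_type == "binary" and prevalence is not None)
    ests, ests_l = [], []
    for r in range(boot_cfg.n_replicates):
        omega = draw_bootstrap_weights(
            n, _sub_seed(boot_cfg.seed, boot_cfg.n_calibration + 1 + r), spread)
        h2, h2_l = _weighted_estimate(x_screened, ph, omega, cfg, prevalence)
        ests.append(h2)
        if liab:
            ests_l.append(h2_l)
    ests = np.asarray(ests)
    if len(ests) < 2:
        raise ValueError("fewer than 2 successful bootstrap replicates")
    result = BootstrapResult(se=_sd(ests), estimates=ests, penalty=penalty)
    if liab:
        arr = np.asarray(ests_l)
        result.se_liability = _sd(arr)
        result.estimates_liability = arr
    return result


def _sd(values: np.ndarray) -> float:
    # identical replicates must report exactly 0, not mean-rounding dust
    if np.ptp(values) == 0.0:
        return 0.0
    return float(np.std(values, ddof=1))


def run_bootstrap(x_screened: np.ndarray, ph: PhenotypeSet,
                  rcv_cfg: RCVConfig, boot_cfg: BootstrapConfig,
                  prevalence: float | None = None,
                  spread: float = 1.0) -> BootstrapResult:
    """Two-phase procedure: calibrate the penalty, then estimate the SE."""
    lam = calibrate_penalty(x_screened, ph, rcv_cfg, boot_cfg, spread)
    return weighted_bootstrap_se(x_screened, ph, lam, rcv_cfg, boot_cfg,
                                 prevalence, spread)


def _sub_seed(seed: int, r: int) -> int:
    return int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % 2**31)


def _base_weights(ph: PhenotypeSet) -> np.ndarray | None:
    if ph.outcome_type != "survival":
        return None
    return ipcw_weights(ph.y, ph.event).weights


def _weighted_estimate(x_screened: np.ndarray, ph: PhenotypeSet,
                       omega: np.ndarray, cfg: RCVConfig,
                       prevalence: float | None
                       ) -> tuple[float, float | None]:
    """One weighted re-estimation of h2 (Steps 2-4 plus total variance)."""
    y = ph.y
    if ph.outcome_type == "survival":
        # the censoring survival function is itself re-estimated under the
        # bootstrap weights, then multiplied into them
        ip = ipcw_weights(y, ph.event, case_weights=omega)
        w = omega * ip.weights
        sigma_total = _weighted_variance(y, w)
    elif ph.outcome_type == "binary":
        w = omega
        dbar = float((omega @ y) / omega.sum())
        sigma_total = dbar * (1.0 - dbar)
    else:
        w = omega
        sigma_total = _weighted_variance(y, w)
    sigma_e = rcv_sigma_e(x_screened, y, cfg, w).sigma_e
    h2 = 1.0 - sigma_e / sigma_total
    h2_l = None
    if ph.outcome_type == "binary" and prevalence is not None:
        P = float((omega @ y) / omega.sum())
        z2 = norm.pdf(norm.ppf(1.0 - prevalence)) ** 2
        h2_l = h2 * prevalence**2 * (1 - prevalence)**2 / (P * (1 - P) * z2)
    return h2, h2_l


def _weighted_variance(y: np.ndarray, w: np.ndarray) -> float:
    v1 = w.sum()
    v2 = w @ w
    ybar = (w @ y) / v1
    return float(v1 * (w @ (y - ybar) ** 2) / (v1**2 - v2))
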