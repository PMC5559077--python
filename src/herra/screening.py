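"""Step 1 — dimensionality reduction of the SNP set below the sample size.

Two screeners are provided.  Sure independence screening (SIS) ranks SNPs by
the magnitude of their (optionally weighted) marginal correlation with the
outcome and keeps the top fraction; it is adequate while the number of SNPs
is moderate (roughly up to 10,000).  Iteratively thresholded ridge
regression screening (ITRRS) repeatedly fits a ridge regression on the
currently retained SNPs and keeps the top fraction by absolute coefficient;
because the fit is joint it accounts for linkage disequilibrium among SNPs
and is the recommended screener for larger panels, run per chromosome and
with the per-chromosome survivors combined.

Both screeners are deterministic given the input order: ties in the ranking
statistic are broken toward the lower SNP index.  The ridge penalty enters
the objective as lambda * N * ||b||^2 on standardized columns, so the same
shrinkage value has comparable meaning across sample sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import StandardizedGenotypes

logger = logging.getLogger("herra")


@dataclass
class ScreeningConfig:
    """Tuning parameters for Step-1 screening.

    keep_fraction is the per-iteration retained fraction (SIS uses a single
    pass); shrinkage is the ridge penalty lambda for ITRRS.
    """

    method: str = "sis"
    keep_fraction: float = 0.3
    n_iterations: int = 1
    shrinkage: float = 0.01
    per_chromosome: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("sis", "itrrs"):
            raise ValueError(f"unknown screening method {self.method!r}")
        if not 0.0 < self.keep_fraction <= 1.0:
            raise ValueError("keep_fraction must be in (0, 1]")
        if self.method == "itrrs":
            if self.n_iterations < 1:
                raise ValueError("itrrs requires n_iterations >= 1")
            if self.shrinkage <= 0:
                raise ValueError("itrrs requires shrinkage > 0")


@dataclass
class SelectedSet:
    """SNPs surviving screening (sorted unique indices into the dataset)."""

    snp_indices: np.ndarray
    per_iteration_sizes: list[int] = field(default_factory=list)
    method: str = ""

    def __len__(self) -> int:
        return len(self.snp_indices)


def default_screening_config(n_snps: int) -> ScreeningConfig:
    """SIS keeping 30% for moderate panels; per-chromosome ITRRS
    (6 iterations, keep 50%) beyond ~10,000 SNPs."""
    if n_snps <= 10_000:
        return ScreeningConfig(method="sis", keep_fraction=0.3)
    return ScreeningConfig(method="itrrs", keep_fraction=0.5,
                           n_iterations=6, shrinkage=0.01)


def _as_matrix(x) -> np.ndarray:
    return x.matrix if isinstance(x, StandardizedGenotypes) else np.asarray(x, float)


def _top_k(stat: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest |stat|, ties broken toward lower index."""
    order = np.lexsort((np.arange(len(stat)), -np.abs(stat)))
    return np.sort(order[:k])


def sis_screen(x, y: np.ndarray, keep_fraction: float,
               weights: np.ndarray | None = None) -> SelectedSet:
    """Marginal correlation screening: keep ceil(keep_fraction * M) SNPs
    with the largest absolute (weighted) sample correlation with y."""
    mat = _as_matrix(x)
    y = np.asarray(y, dtype=float)
    n, m = mat.shape
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    ybar = (w @ y) / wsum
    yc = y - ybar
    sy2 = w @ yc**2
    if sy2 <= 0:
        raise ValueError("outcome has zero (weighted) variance")
    xbar = (w @ mat) / wsum
    num = (w * yc) @ mat                      # sum_i w_i (x_ij - xbar_j) yc_i
    xvar = w @ mat**2 - wsum * xbar**2
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = num / np.sqrt(np.maximum(xvar, 0.0) * sy2)
    corr = np.nan_to_num(corr, nan=0.0, posinf=0.0, neginf=0.0)
    k = math.ceil(keep_fraction * m)
    idx = _top_k(corr, k)
    return SelectedSet(snp_indices=idx, per_iteration_sizes=[k], method="sis")


def ridge_fit(x: np.ndarray, y: np.ndarray, shrinkage: float,
              weights: np.ndarray | None = None) -> np.ndarray:
    """Ridge coefficients minimizing sum_i w_i (y_i - a - x_i b)^2
    + shrinkage * N * ||b||^2, with the intercept a unpenalized.

    Solved in the primal (p <= n) or dual (p > n) form, so any column
    count is handled exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if shrinkage <= 0:
        raise ValueError("shrinkage must be > 0")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs to ridge_fit")
    n, p = x.shape
    lam = shrinkage * n
    if weights is None:
        xbar, ybar = x.mean(axis=0), y.mean()
        sw = None
    else:
        w = np.asarray(weights, dtype=float)
        wsum = w.sum()
        xbar, ybar = (w @ x) / wsum, (w @ y) / wsum
        sw = np.sqrt(w)
    xc = x - xbar
    yc = y - ybar
    if sw is not None:
        xc = xc * sw[:, None]
        yc = yc * sw
    if p <= n:
        gram = xc.T @ xc
        gram.flat[:: p + 1] += lam
        return np.linalg.solve(gram, xc.T @ yc)
    outer = xc @ xc.T
    outer.flat[:: n + 1] += lam
    return xc.T @ np.linalg.solve(outer, yc)


def itrrs_screen(x, y: np.ndarray, chrom_labels: np.ndarray,
                 config: ScreeningConfig,
                 weights: np.ndarray | None = None) -> SelectedSet:
    """Iteratively thresholded ridge regression screening, per chromosome.

    Within each chromosome the ridge fit is recomputed on the currently
    retained SNPs and the top ceil(keep_fraction * m) by |coefficient| are
    kept, for n_iterations rounds; the per-chromosome survivors are
    combined.  With per_chromosome=False all SNPs are treated as one block.
    """
    mat = _as_matrix(x)
    chrom_labels = np.asarray(chrom_labels)
    if config.method != "itrrs":
        raise ValueError("itrrs_screen requires config.method == 'itrrs'")
    if config.per_chromosome:
        # preserve order of first appearance so labels need not sort cleanly
        _, first = np.unique(chrom_labels, return_index=True)
        blocks = [np.flatnonzero(chrom_labels == chrom_labels[i])
                  for i in np.sort(first)]
    else:
        blocks = [np.arange(mat.shape[1])]

    survivors_per_block: list[np.ndarray] = []
    sizes = np.zeros(config.n_iterations, dtype=int)
    for block in blocks:
        retained = block
        for it in range(config.n_iterations):
            if len(retained) == 0:
                logger.warning("itrrs: chromosome block emptied at iteration %d",
                               it)
                break
            coefs = ridge_fit(mat[:, retained], y, config.shrinkage, weights)
            k = math.ceil(config.keep_fraction * len(retained))
            retained = retained[_top_k(coefs, k)]
            sizes[it] += len(retained)
        survivors_per_block.append(retained)
    idx = np.sort(np.concatenate(survivors_per_block))
    return SelectedSet(snp_indices=idx,
                       per_iteration_sizes=[int(s) for s in sizes],
                       method="itrrs")


def screen(x, y: np.ndarray, chrom_labels: np.ndarray,
           config: ScreeningConfig,
           weights: np.ndarray | None = None) -> SelectedSet:
    """Dispatch to the configured screener."""
    if config.method == "sis":
        return sis_screen(x, y, config.keep_fraction, weights)
    return itrrs_screen(x, y, chrom_labels, config, weights)
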