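"""Synthetic GWAS data generator for exercising every estimator path.

Genotypes come from a haplotype pool with local linkage disequilibrium:
each pool haplotype is a first-order binary Markov chain along the
chromosome whose adjacent-allele correlation is ``ld_decay``, so the
correlation between alleles d SNPs apart decays as ld_decay**d.  Allele
frequencies follow a slowly varying reflected random walk inside
``maf_range`` — tightly linked SNPs in real LD blocks share allele
frequencies (a tag with r^2 near 1 must match the MAF of the SNP it tags),
and near-equal adjacent frequencies are also what lets the chain attain
the nominal correlation without truncating transition probabilities.
Haplotypes are drawn from the pool with replacement and paired to form
diploid genotypes, adding the bounded haplotype diversity that pool
resampling of real phased chromosomes produces.

The trait model is additive on standardized causal genotypes:
Y = mu + sum_j X_j u_j + e with e ~ N(0, sigma_e2) and effects
u_j ~ N(0, sigma_g2 / p) where sigma_g2 = h2 * sigma_e2 / (1 - h2), so the
realized sum of squared effects equals sigma_g2 in expectation (exactly,
in exact-normalization mode).  Binary traits threshold Y at the upper-K
theoretical quantile; age-at-onset traits treat Y as log failure time and
censor with N(0, censor_sd^2) log-scale censoring times (sd 2 gives ~50%
censoring at the default trait scale).  The "untyped causal" scenario
removes each causal SNP and its flanking neighbors from the analyzed
panel, leaving only LD proxies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .genotype_io import GenotypeDataset, PhenotypeSet

_SIM_CHROM_OFFSET = 1  # chromosome labels start at "1"


@dataclass
class SimulationConfig:
    """Design of one simulated dataset (sizes, genetics, outcome, LD)."""

    n_samples: int = 1000
    n_snps: int = 1000
    n_chromosomes: int = 1
    n_causal: int = 50
    h2_true: float = 0.3
    sigma_e2: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_maf_max: float | None = None
    scenario: str = "typed"
    flank_exclusion: int = 5
    outcome: str = "continuous"
    binary_K: float = 0.5
    censor_sd: float = 2.0
    haplotype_pool_size: int = 2000
    ld_decay: float = 0.5
    mu: float = 0.0
    exact_normalization: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if self.scenario not in ("typed", "maf_restricted", "untyped_causal"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must be in [0, 1)")
        if self.haplotype_pool_size % 2:
            raise ValueError("haplotype_pool_size must be even")
        if not 0.0 < self.h2_true < 1.0:
            raise ValueError("h2_true must be in (0, 1)")

    @property
    def sigma_g2(self) -> float:
        return self.h2_true * self.sigma_e2 / (1.0 - self.h2_true)


@dataclass
class SimulationTruth:
    """Ground truth of one replicate, for recovery tests."""

    causal_indices: np.ndarray
    effects: np.ndarray
    sigma_g2: float
    h2_true: float
    genetic_values: np.ndarray
    observed_snp_indices: np.ndarray = field(default_factory=lambda: np.zeros(0,
                                                                              int))


def _chromosome_blocks(m: int, k: int) -> list[np.ndarray]:
    bounds = np.linspace(0, m, k + 1).astype(int)
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(k)]


_FREQ_WALK_STEP = 0.02  # per-SNP drift of the allele-frequency walk


def _frequency_walk(m: int, maf_range: tuple[float, float],
                    rng: np.random.Generator) -> np.ndarray:
    """Allele frequencies as a reflected Gaussian random walk in maf_range."""
    lo, hi = maf_range
    steps = rng.normal(0.0, _FREQ_WALK_STEP, size=m)
    steps[0] = rng.uniform(lo, hi)
    f = np.cumsum(steps)
    # reflect into [lo, hi]
    span = hi - lo
    f = lo + span - np.abs((f - lo) % (2 * span) - span)
    return f


def simulate_genotypes(cfg: SimulationConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[GenotypeDataset, np.ndarray]:
    """Build the haplotype pool and draw paired haplotypes into genotypes.

    Returns the dataset and the pool (pool_size x M allele matrix).
    Chromosomes are generated independently, and haplotypes are drawn
    independently per chromosome.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    h = cfg.haplotype_pool_size
    n, m = cfg.n_samples, cfg.n_snps
    rho = cfg.ld_decay
    blocks = _chromosome_blocks(m, cfg.n_chromosomes)

    pool = np.empty((h, m), dtype=np.int8)
    genotypes = np.empty((n, m), dtype=np.float64)
    chrom = np.empty(m, dtype=object)
    freqs = np.empty(m)
    for c, block in enumerate(blocks):
        mb = len(block)
        f = _frequency_walk(mb, cfg.maf_range, rng)
        freqs[block] = f
        sd = np.sqrt(f * (1.0 - f))
        alleles = np.empty((h, mb), dtype=np.int8)
        u = rng.random((h, mb))
        alleles[:, 0] = u[:, 0] < f[0]
        for j in range(1, mb):
            # conditional mean preserving corr(a_{j-1}, a_j) = rho; with the
            # slowly varying frequencies the clip is almost never active
            slope = rho * sd[j] / sd[j - 1]
            p = np.clip(f[j] + slope * (alleles[:, j - 1] - f[j - 1]), 0.0, 1.0)
            alleles[:, j] = u[:, j] < p
        pool[:, block] = alleles
        draws = rng.integers(0, h, size=2 * n)
        genotypes[:, block] = (alleles[draws[:n]] + alleles[draws[n:]])
        chrom[block] = str(c + _SIM_CHROM_OFFSET)

    emp_freq = genotypes.mean(axis=0) / 2.0
    maf = np.minimum(emp_freq, 1.0 - emp_freq)
    keep = maf > 0.0
    dataset = GenotypeDataset(
        genotypes=genotypes[:, keep],
        snp_chrom=chrom[keep].astype(str),
        snp_id=np.array([f"snp{j:06d}" for j in range(m)])[keep],
        sample_id=np.array([f"ind{i:06d}" for i in range(n)]),
        maf=maf[keep],
    )
    return dataset, pool[:, keep]


def draw_causal_effects(cfg: SimulationConfig, g: GenotypeDataset,
                        rng: np.random.Generator | None = None
                        ) -> SimulationTruth:
    """Pick causal SNPs (optionally MAF-restricted) and draw their effects
    on the standardized-genotype scale."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    available = np.arange(g.n_snps)
    theta = cfg.causal_maf_max
    if cfg.scenario == "maf_restricted" or theta is not None:
        if theta is None:
            raise ValueError("maf_restricted scenario requires causal_maf_max")
        available = available[g.maf[available] <= theta]
        if len(available) < cfg.n_causal:
            raise ValueError(
                f"only {len(available)} SNPs with MAF <= {theta}; "
                f"{cfg.n_causal} causal SNPs requested")
    causal = np.sort(rng.choice(available, size=cfg.n_causal, replace=False))
    u = rng.normal(0.0, np.sqrt(cfg.sigma_g2 / cfg.n_causal),
                   size=cfg.n_causal)
    if cfg.exact_normalization:
        u *= np.sqrt(cfg.sigma_g2 / np.sum(u**2))
    xc = g.genotypes[:, causal]
    xs = (xc - xc.mean(axis=0)) / xc.std(axis=0, ddof=1)
    return SimulationTruth(
        causal_indices=causal, effects=u,
        sigma_g2=float(np.sum(u**2)), h2_true=cfg.h2_true,
        genetic_values=xs @ u,
        observed_snp_indices=np.arange(g.n_snps),
    )


def simulate_phenotype(g: GenotypeDataset, truth: SimulationTruth,
                       cfg: SimulationConfig,
                       rng: np.random.Generator | None = None) -> PhenotypeSet:
    """Generate the outcome from the additive model on standardized causal
    genotypes, in the configured flavour."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    e = rng.normal(0.0, np.sqrt(cfg.sigma_e2), size=g.n_samples)
    y = cfg.mu + truth.genetic_values + e
    ids = g.sample_id
    if cfg.outcome == "continuous":
        return PhenotypeSet("continuous", y, sample_id=ids)
    if cfg.outcome == "binary":
        sigma_y2 = cfg.sigma_g2 + cfg.sigma_e2
        thr = cfg.mu + np.sqrt(sigma_y2) * norm.ppf(1.0 - cfg.binary_K)
        return PhenotypeSet("binary", (y > thr).astype(float), sample_id=ids)
    if cfg.outcome == "survival":
        c = rng.normal(0.0, cfg.censor_sd, size=g.n_samples)
        observed = np.minimum(y, c)
        delta = (y <= c).astype(float)
        return PhenotypeSet("survival", observed, event=delta, sample_id=ids)
    raise ValueError(f"unknown outcome {cfg.outcome!r}")


def apply_scenario_exclusions(g: GenotypeDataset, truth: SimulationTruth,
                              cfg: SimulationConfig
                              ) -> tuple[GenotypeDataset, SimulationTruth]:
    """Under the untyped-causal scenario, drop every causal SNP plus
    flank_exclusion neighbors per side (within-chromosome, clipped at
    chromosome ends); otherwise the identity."""
    if cfg.scenario != "untyped_causal":
        truth.observed_snp_indices = np.arange(g.n_snps)
        return g, truth
    drop = np.zeros(g.n_snps, dtype=bool)
    f = cfg.flank_exclusion
    for j in truth.causal_indices:
        lo, hi = max(0, j - f), min(g.n_snps, j + f + 1)
        window = np.arange(lo, hi)
        drop[window[g.snp_chrom[window] == g.snp_chrom[j]]] = True
    kept = np.flatnonzero(~drop)
    truth.observed_snp_indices = kept
    return g.subset_snps(kept), truth


def simulate_dataset(cfg: SimulationConfig
                     ) -> tuple[GenotypeDataset, PhenotypeSet, SimulationTruth]:
    """One full replicate: genotypes, effects, outcome, scenario exclusions.

    The returned dataset contains only the observed (post-exclusion) SNPs;
    the truth records the mapping back to the full panel.
    """
    rng = np.random.default_rng(cfg.seed)
    g, _ = simulate_genotypes(cfg, rng)
    truth = draw_causal_effects(cfg, g, rng)
    ph = simulate_phenotype(g, truth, cfg, rng)
    g_obs, truth = apply_scenario_exclusions(g, truth, cfg)
    return g_obs, ph, truth
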