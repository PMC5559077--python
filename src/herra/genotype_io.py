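"""Reading PLINK-format genotypes and phenotype/covariate tables.

Genotypes are held as an N x M additive allele-count matrix (counts of the
.bim A1 allele, so 0/1/2 per biallelic SNP).  Missing calls are mean-imputed
per SNP on load; monomorphic SNPs are dropped.  Standardization centers and
scales each SNP column to sample mean 0 and sample variance 1 (N-1
denominator), the scale on which all downstream regression steps operate.
Heritability is invariant to which allele is counted, so no minor-allele
re-orientation is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("herra")

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes -> A1 allele count; code 1 is the missing marker.
_CODE_TO_COUNT = np.array([2.0, np.nan, 1.0, 0.0])
_COUNT_TO_CODE = {2: 0, 1: 2, 0: 3}


class PlinkFormatError(ValueError):
    """Malformed .bed payload (bad magic bytes or mode)."""


class ConsistencyError(ValueError):
    """Mutually inconsistent .bed/.bim/.fam triplet."""


class DegenerateSNPError(ValueError):
    """A SNP column with zero variance where variation is required."""


class PhenotypeValidationError(ValueError):
    """Phenotype table violating the declared outcome type."""


@dataclass
class GenotypeDataset:
    """Additive genotype matrix plus per-SNP / per-sample metadata.

    ``genotypes`` holds A1 allele counts as float64; entries are in
    {0, 1, 2} except where a missing call was imputed to the SNP mean
    (``n_imputed`` counts those).
    """

    genotypes: np.ndarray
    snp_chrom: np.ndarray
    snp_id: np.ndarray
    sample_id: np.ndarray
    maf: np.ndarray
    n_imputed: int = 0

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def __post_init__(self) -> None:
        m = self.genotypes.shape[1]
        for name in ("snp_chrom", "snp_id", "maf"):
            if len(getattr(self, name)) != m:
                raise ConsistencyError(f"{name} has length "
                                       f"{len(getattr(self, name))}, expected {m}")
        if len(self.sample_id) != self.genotypes.shape[0]:
            raise ConsistencyError("sample_id length does not match genotype rows")

    def subset_snps(self, indices: np.ndarray) -> "GenotypeDataset":
        idx = np.asarray(indices, dtype=int)
        return GenotypeDataset(
            genotypes=self.genotypes[:, idx],
            snp_chrom=self.snp_chrom[idx],
            snp_id=self.snp_id[idx],
            sample_id=self.sample_id,
            maf=self.maf[idx],
            n_imputed=self.n_imputed,
        )


@dataclass
class StandardizedGenotypes:
    """Column-standardized genotype matrix (mean 0, variance 1, ddof=1)."""

    matrix: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray


@dataclass
class PhenotypeSet:
    """Outcome vector in one of three flavours, aligned to genotype samples.

    For survival outcomes ``y`` is the log-scale observed time
    min(log T, C) and ``event`` the indicator that the failure (not the
    censoring) was observed.
    """

    outcome_type: str
    y: np.ndarray
    event: np.ndarray | None = None
    covariates: np.ndarray | None = None
    covariate_names: list[str] | None = None
    sample_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.outcome_type not in ("continuous", "binary", "survival"):
            raise PhenotypeValidationError(
                f"unknown outcome_type {self.outcome_type!r}")
        self.y = np.asarray(self.y, dtype=float)
        if not np.all(np.isfinite(self.y)):
            raise PhenotypeValidationError("non-finite outcome values")
        if self.outcome_type == "binary" and not np.isin(self.y, (0.0, 1.0)).all():
            raise PhenotypeValidationError("binary outcome must be coded 0/1")
        if self.outcome_type == "survival":
            if self.event is None:
                raise PhenotypeValidationError(
                    "survival outcome requires an event indicator")
            self.event = np.asarray(self.event, dtype=float)
            if not np.isin(self.event, (0.0, 1.0)).all():
                raise PhenotypeValidationError("event indicator must be 0/1")


# ---------------------------------------------------------------------------
# PLINK v1 binary triplet
# ---------------------------------------------------------------------------

def _decode_bed(raw: bytes, n_samples: int, n_snps: int) -> np.ndarray:
    """Unpack SNP-major 2-bit codes into an N x M float matrix (NaN=missing)."""
    if raw[:3] != _PLINK_MAGIC:
        raise PlinkFormatError("bad .bed magic bytes (expected 0x6c 0x1b 0x01, "
                               "SNP-major PLINK v1)")
    bytes_per_snp = (n_samples + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * n_snps:
        raise ConsistencyError(
            f".bed payload of {body.size} bytes does not match "
            f"N={n_samples}, M={n_snps} from .fam/.bim")
    body = body.reshape(n_snps, bytes_per_snp)
    # interleave the four 2-bit fields, low bits = first sample
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    return _CODE_TO_COUNT[codes[:, :n_samples]].T.copy()


def _encode_bed(genotypes: np.ndarray) -> bytes:
    n, m = genotypes.shape
    codes = np.ones((m, ((n + 3) // 4) * 4), dtype=np.uint8)  # 1 = missing
    gt = genotypes.T
    for count, code in _COUNT_TO_CODE.items():
        codes[:, :n][gt == count] = code
    codes = codes.reshape(m, -1, 4)
    packed = (codes[:, :, 0] | (codes[:, :, 1] << 2)
              | (codes[:, :, 2] << 4) | (codes[:, :, 3] << 6))
    return _PLINK_MAGIC + packed.astype(np.uint8).tobytes()



def _ext(prefix: Path, ext: str) -> Path:
    # Path.with_suffix mangles prefixes containing dots; plain append is right
    return prefix.parent / (prefix.name + ext)

def read_plink(prefix: str | Path) -> GenotypeDataset:
    """Read a PLINK v1 ``prefix.bed/.bim/.fam`` triplet.

    Missing genotypes are imputed to the per-SNP mean of the non-missing
    calls; SNPs monomorphic among non-missing calls are dropped.  MAF is
    computed from non-missing calls before imputation.
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not _ext(prefix, ext).exists():
            raise FileNotFoundError(f"missing PLINK file: {_ext(prefix, ext)}")
    bim = pd.read_csv(_ext(prefix, ".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "bp", "a1", "a2"],
                      dtype={"chrom": str, "id": str})
    fam = pd.read_csv(_ext(prefix, ".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"iid": str})
    raw = _ext(prefix, ".bed").read_bytes()
    geno = _decode_bed(raw, len(fam), len(bim))

    n_missing = int(np.isnan(geno).sum())
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(geno, axis=0)
    freq = col_mean / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    # all-missing columns have NaN maf/sd; an all-heterozygote column has
    # maf 0.5 but zero variance, so filter on the variance of non-missing calls
    with np.errstate(invalid="ignore"):
        col_sd = np.nanstd(geno, axis=0)
    poly = (np.nan_to_num(maf, nan=0.0) > 0.0) & (np.nan_to_num(col_sd) > 0.0)
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("read_plink: dropped %d monomorphic SNP(s)", n_dropped)
    if n_missing:
        logger.info("read_plink: imputed %d missing genotype call(s) "
                    "to SNP means", n_missing)
        ii, jj = np.where(np.isnan(geno))
        geno[ii, jj] = col_mean[jj]
    return GenotypeDataset(
        genotypes=np.ascontiguousarray(geno[:, poly]),
        snp_chrom=bim["chrom"].to_numpy()[poly],
        snp_id=bim["id"].to_numpy()[poly],
        sample_id=fam["iid"].to_numpy(),
        maf=maf[poly],
        n_imputed=n_missing,
    )


def write_plink(dataset: GenotypeDataset, prefix: str | Path) -> None:
    """Write ``prefix.bed/.bim/.fam`` (PLINK v1, SNP-major).

    Genotype entries must be 0/1/2 or NaN (written as missing); imputed
    fractional values cannot be represented and raise an error.
    """
    prefix = Path(prefix)
    gt = dataset.genotypes
    ok = np.isnan(gt) | np.isin(gt, (0.0, 1.0, 2.0))
    if not ok.all():
        raise ValueError("write_plink requires integer 0/1/2 (or NaN) genotypes")
    _ext(prefix, ".bed").write_bytes(_encode_bed(gt))
    m = dataset.n_snps
    bim = pd.DataFrame({
        "chrom": dataset.snp_chrom, "id": dataset.snp_id,
        "cm": np.zeros(m), "bp": np.arange(1, m + 1),
        "a1": ["A"] * m, "a2": ["B"] * m,
    })
    bim.to_csv(_ext(prefix, ".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": dataset.sample_id, "iid": dataset.sample_id,
        "father": 0, "mother": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(_ext(prefix, ".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize(g: GenotypeDataset | np.ndarray) -> StandardizedGenotypes:
    """Center and scale each SNP column to mean 0, variance 1 (ddof=1)."""
    matrix = g.genotypes if isinstance(g, GenotypeDataset) else np.asarray(g, float)
    if np.isnan(matrix).any():
        raise ValueError("standardize requires imputed (non-missing) genotypes")
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1)
    degenerate = sds == 0.0
    if degenerate.any():
        j = int(np.flatnonzero(degenerate)[0])
        snp = (g.snp_id[j] if isinstance(g, GenotypeDataset) else f"column {j}")
        raise DegenerateSNPError(f"constant genotype column: {snp}")
    return StandardizedGenotypes(matrix=(matrix - means) / sds,
                                 column_means=means, column_sds=sds)


# ---------------------------------------------------------------------------
# Phenotype / covariate tables
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path,
                    outcome_type: str,
                    sample_ids: np.ndarray | None = None,
                    covariate_path: str | Path | None = None,
                    value_col: str | None = None,
                    time_col: str = "time",
                    status_col: str = "status") -> PhenotypeSet:
    """Read a delimited phenotype table and align it to genotype order.

    The first column is the sample ID.  Continuous/binary outcomes take the
    value from ``value_col`` (default: second column); survival outcomes
    need ``time_col`` (times > 0, log taken internally) and ``status_col``
    (1 = event).  Samples in ``sample_ids`` missing from the table raise an
    error listing the absent IDs.
    """
    tab = pd.read_csv(path, sep=r"\s+", dtype={0: str})
    id_col = tab.columns[0]
    tab[id_col] = tab[id_col].astype(str)
    if sample_ids is not None:
        wanted = pd.Index(np.asarray(sample_ids, dtype=str), name=id_col)
        missing = wanted.difference(tab[id_col])
        if len(missing):
            raise PhenotypeValidationError(
                "samples present in genotypes but absent from phenotype file: "
                + ", ".join(map(str, missing[:20])))
        tab = tab.set_index(id_col).loc[wanted].reset_index()
    ids = tab[id_col].to_numpy()

    event = None
    if outcome_type == "survival":
        for col in (time_col, status_col):
            if col not in tab.columns:
                raise PhenotypeValidationError(
                    f"survival outcome requires a {col!r} column")
        times = tab[time_col].to_numpy(dtype=float)
        if np.any(times <= 0):
            raise PhenotypeValidationError("survival times must be positive")
        y = np.log(times)
        event = tab[status_col].to_numpy(dtype=float)
    else:
        col = value_col if value_col is not None else tab.columns[1]
        y = tab[col].to_numpy(dtype=float)

    covariates = covariate_names = None
    if covariate_path is not None:
        cov = pd.read_csv(covariate_path, sep=r"\s+", dtype={0: str})
        cov_id = cov.columns[0]
        cov[cov_id] = cov[cov_id].astype(str)
        missing = pd.Index(ids).difference(cov[cov_id])
        if len(missing):
            raise PhenotypeValidationError(
                "samples absent from covariate file: "
                + ", ".join(map(str, missing[:20])))
        cov = cov.set_index(cov_id).loc[ids]
        covariate_names = list(cov.columns)
        covariates = cov.to_numpy(dtype=float)

    return PhenotypeSet(outcome_type=outcome_type, y=y, event=event,
                        covariates=covariates, covariate_names=covariate_names,
                        sample_id=ids)
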