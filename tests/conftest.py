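import numpy as np
import pytest

from herra import GenotypeDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_dataset(rng, n=16, m=9, missing=0):
    """Small polymorphic genotype dataset; optionally NaN-out some entries."""
    while True:
        geno = rng.binomial(2, rng.uniform(0.2, 0.5, size=m),
                            size=(n, m)).astype(float)
        if all(len(np.unique(geno[:, j])) > 1 for j in range(m)):
            break
    if missing:
        flat = rng.choice(n * m, size=missing, replace=False)
        geno[np.unravel_index(flat, geno.shape)] = np.nan
    freq = np.nanmean(geno, axis=0) / 2
    return GenotypeDataset(
        genotypes=geno,
        snp_chrom=np.array(["1"] * (m // 2) + ["2"] * (m - m // 2)),
        snp_id=np.array([f"rs{j}" for j in range(m)]),
        sample_id=np.array([f"s{i}" for i in range(n)]),
        maf=np.minimum(freq, 1 - freq),
    )
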