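import math

import numpy as np
import pytest

from iloci.genotype_io import MISSING, GenotypeMatrix, PhenotypeLabels


def make_matrix(codes, sample_status=None, snp_ids=None):
    """Build a GenotypeMatrix (+labels if status given) from a code array."""
    codes = np.asarray(codes, dtype=np.int8)
    n_snps, n_samples = codes.shape
    ids = snp_ids or [f"rs{i + 1}" for i in range(n_snps)]
    gm = GenotypeMatrix(
        snp_ids=ids,
        chrom=["1"] * n_snps,
        pos=np.arange(n_snps, dtype=np.int64) * 1000,
        alleles=[("A", "G")] * n_snps,
        genotypes=codes,
        sample_ids=[f"s{j + 1}" for j in range(n_samples)],
    )
    if sample_status is None:
        return gm
    labels = PhenotypeLabels(gm.sample_ids, np.asarray(sample_status, dtype=bool))
    return gm, labels


def rho_oracle(gx, gy, group_mask):
    """Individual-level oracle: E[xy]/sqrt(E[x^2] E[y^2]) on {-1,0,+1} codes.

    Independent of the table-based implementation path: encodes genotypes
    directly and averages products over pairwise-complete group members.
    """
    gx = np.asarray(gx)
    gy = np.asarray(gy)
    use = np.asarray(group_mask, dtype=bool) & (gx != MISSING) & (gy != MISSING)
    if not use.any():
        return math.nan
    x = gx[use].astype(float) - 1.0
    y = gy[use].astype(float) - 1.0
    ex2 = float(np.mean(x * x))
    ey2 = float(np.mean(y * y))
    if ex2 == 0.0 or ey2 == 0.0:
        return math.nan
    return float(np.mean(x * y)) / math.sqrt(ex2 * ey2)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_case_control(rng, n_snps, n_samples, missing_rate=0.0):
    """Random genotype matrix + balanced labels for property tests."""
    codes = rng.integers(0, 3, size=(n_snps, n_samples)).astype(np.int8)
    if missing_rate > 0:
        codes[rng.random(codes.shape) < missing_rate] = MISSING
    status = np.zeros(n_samples, dtype=bool)
    status[: n_samples // 2] = True
    gm, labels = make_matrix(codes, sample_status=status)
    return gm, labels
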