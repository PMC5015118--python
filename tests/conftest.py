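import numpy as np
import pytest

from fastbat.io_formats import GenotypePanel


def make_panel(genotypes, positions=None, chrom="1", prefix="snp"):
    """Build a GenotypePanel straight from a genotype matrix."""
    g = np.asarray(genotypes, dtype=float)
    n, m = g.shape
    if positions is None:
        positions = np.arange(1, m + 1)
    return GenotypePanel(
        sample_ids=[f"s{i}" for i in range(n)],
        snp_ids=[f"{prefix}{j + 1}" for j in range(m)],
        chromosomes=np.array([chrom] * m, dtype=object),
        positions=np.asarray(positions, dtype=int),
        allele1=np.array(["A"] * m, dtype=object),
        allele2=np.array(["G"] * m, dtype=object),
        genotypes=g,
    )


@pytest.fixture
def toy_panel():
    """6 samples x 3 SNPs with hand-checkable correlations."""
    g = [[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2], [1, 0, 1], [2, 2, 0]]
    return make_panel(g)


def random_corr(m, rng, n_factor=5):
    """Random well-conditioned correlation matrix: sample correlation of
    n_factor*m Gaussian vectors."""
    a = rng.standard_normal((m, n_factor * m))
    return np.corrcoef(a)
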