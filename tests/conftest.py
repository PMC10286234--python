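import numpy as np
import pandas as pd
import pytest

from hmkpop.containers import GenotypeMatrix, PoolCountMatrix


@pytest.fixture
def two_pool_meta():
    return pd.DataFrame(
        {
            "pool_id": ["A", "B"],
            "n_individuals": [50, 50],
            "latitude": [54.0, 43.0],
            "longitude": [-10.0, -3.0],
            "group_label": ["north", "south"],
            "year": [2016, 2016],
        }
    )


@pytest.fixture
def tiny_counts(two_pool_meta):
    """3 SNPs x 2 pools with easily checkable depths."""
    snps = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "pos": [100, 250, 50],
            "ref": ["A", "C", "G"],
            "alt": ["G", "T", "A"],
        }
    )
    return PoolCountMatrix(
        snps=snps,
        ref_count=np.array([[30, 12], [7, 0], [0, 20]]),
        alt_count=np.array([[10, 8], [3, 0], [40, 20]]),
        pools=two_pool_meta,
    )


def make_genotypes(geno, sites=None, chrom=None, pos=None):
    """Build a GenotypeMatrix from a raw dosage array."""
    geno = np.asarray(geno, dtype=float)
    n, m = geno.shape
    sites = sites if sites is not None else ["S1"] * n
    individuals = pd.DataFrame(
        {"individual_id": [f"ind{i}" for i in range(n)], "site": sites}
    )
    snps = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["chr1"] * m,
            "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
        }
    )
    return GenotypeMatrix(individuals=individuals, snps=snps, geno=geno)
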