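import numpy as np
import pandas as pd
import pytest

from episcan.types import GenotypeDataset


def make_dataset(genotypes, phenotype=None, cohort="X", positions=None, chrom="1"):
    """Build a GenotypeDataset from a raw dosage matrix for tests."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    if phenotype is None:
        phenotype = np.zeros(n, dtype=int)
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{k}" for k in range(n)],
            "cohort": cohort,
            "phenotype": np.asarray(phenotype, dtype=int),
        }
    )
    if positions is None:
        positions = 10_000 * np.arange(m) + 1
    snps = pd.DataFrame(
        {
            "snp_id": [f"v{k}" for k in range(m)],
            "chrom": chrom,
            "pos": positions,
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeDataset(genotypes=g, samples=samples, snps=snps)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dataset(rng, n=100, m=20, maf=0.3, case_fraction=0.5, missing_rate=0.0):
    g = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    if missing_rate > 0:
        g[rng.random((n, m)) < missing_rate] = -1
    phen = (rng.random(n) < case_fraction).astype(int)
    return make_dataset(g, phen)
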