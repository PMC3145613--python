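import numpy as np
import pandas as pd
import pytest

from genewise.data import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genotypes(dosages, positions=None, chrom="1", ids=None, imputed=False):
    """Build a GenotypeMatrix from a raw dosage array (test helper)."""
    d = np.asarray(dosages, dtype=float)
    n, p = d.shape
    if positions is None:
        positions = 1000 * (np.arange(p) + 1)
    variants = pd.DataFrame(
        {
            "id": [f"snp{j + 1}" for j in range(p)],
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "G",
            "maf": [
                min(m, 1 - m)
                for m in (np.nanmean(d, axis=0) / 2.0)
            ],
            "imputed": imputed,
        }
    )
    if ids is None:
        ids = np.array([f"ind{i + 1}" for i in range(n)])
    return GenotypeMatrix(d, variants, np.asarray(ids))


@pytest.fixture
def genotype_factory():
    return make_genotypes
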