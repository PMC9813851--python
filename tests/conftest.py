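import numpy as np
import pandas as pd
import pytest

from vascgwas.genome import Genome, toy_genome
from vascgwas.types import GenotypeMatrix


@pytest.fixture(scope="session")
def genome() -> Genome:
    return toy_genome()


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    return Genome((("1", 1_000_000), ("2", 3_000_000)))


def make_matrix(dosages, chrs=None, bps=None, a1=None, a2=None, ids=None):
    """Hand-built GenotypeMatrix for toy examples (NaN = missing)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrs = chrs or ["1"] * m
    bps = bps or list(range(1000, 1000 + m))
    a1 = a1 or ["A"] * m
    a2 = a2 or ["C"] * m
    snps = pd.DataFrame({"chr": chrs, "bp": bps, "a1": a1, "a2": a2})
    snps.insert(0, "id", snps["chr"].astype(str) + ":" + snps["bp"].astype(str))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        snps["freq"] = np.nanmean(dosages, axis=0) / 2.0
    sample_ids = ids or [f"S{i:03d}" for i in range(n)]
    return GenotypeMatrix(sample_ids, snps, dosages)


@pytest.fixture
def tiny_matrix():
    return make_matrix([[0, 1, 2, 1], [1, 1, 0, 0], [2, 0, 0, np.nan]])
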