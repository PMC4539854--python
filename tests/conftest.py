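import numpy as np
import pandas as pd
import pytest

from sireimpute.containers import GenotypeMatrix, Pedigree, make_snp_table


def make_geno(calls, animals=None, pos_cm=None, pos_bp=None, snp_ids=None):
    """Build a GenotypeMatrix from a nested list / array of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    animals = animals or [f"a{i}" for i in range(n)]
    snp_ids = snp_ids or [f"s{j}" for j in range(m)]
    snps = make_snp_table(snp_ids, pos_bp=pos_bp, pos_cm=pos_cm)
    if pos_cm is None:
        snps["pos_cm"] = np.arange(m, dtype=float)  # 1 cM spacing default
    return GenotypeMatrix(animals, snps, calls)


@pytest.fixture
def geno_factory():
    return make_geno


def make_pedigree(records, generations=None):
    """records: list of (animal, sire, dam, generation) tuples."""
    tab = pd.DataFrame(records, columns=["animal", "sire", "dam", "generation"])
    return Pedigree(tab, generations=generations or [])


@pytest.fixture
def pedigree_factory():
    return make_pedigree
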