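import numpy as np
import pytest

from comorbnet import grn as grn_mod
from comorbnet import synth
from comorbnet.io import LDTable


@pytest.fixture(scope="session")
def bundle():
    """One full synthetic input bundle shared across tests (seed 1)."""
    return synth.generate_all(synth.SynthConfig(seed=1))


@pytest.fixture(scope="session")
def cohort(bundle):
    return bundle["cohort"]


@pytest.fixture(scope="session")
def grn_df(bundle, cohort):
    return grn_mod.build_grn(cohort.genotypes, cohort.expression,
                             cohort.hic_support, cohort.snps, cohort.genes)


@pytest.fixture(scope="session")
def ld(bundle):
    return LDTable(bundle["ld"])


@pytest.fixture(scope="session")
def positions(cohort):
    return dict(zip(cohort.snps["snp"], cohort.snps["pos"].astype(int)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240123)
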