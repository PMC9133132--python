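import numpy as np
import pytest
from hypothesis import settings

from polpause import simulate as sim
from polpause.annotation import GeneModel

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_genome():
    """A small synthetic genome shared by pipeline-level tests."""
    cfg = sim.GenomeConfig(n_rdh=10, n_snrna=6, n_snorna=6, n_coding=8)
    return sim.simulate_genome(cfg, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def plus_gene():
    return GeneModel("gplus", "chr1", 1000, 2000, "+", "protein_coding")


@pytest.fixture
def minus_gene():
    return GeneModel("gminus", "chr1", 1000, 2000, "-", "protein_coding")
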