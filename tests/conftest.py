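import warnings

import numpy as np
import pytest

import eqtmscan as eq

# rank-deficiency warnings from small desk-scale H estimates are expected
warnings.filterwarnings("ignore", message="H is rank-deficient")


@pytest.fixture(scope="session")
def fixture_genome():
    """Toy genome whose CpG/gene placement covers every detailed category."""
    return eq.generate_genome(2, 3, 1.0, seed=2)


@pytest.fixture(scope="session")
def null_cohort(fixture_genome):
    """No confounders, nothing planted: a pure-null cohort."""
    return eq.generate_cohort(fixture_genome, 80, 0, [], seed=7)


@pytest.fixture(scope="session")
def plus_gene():
    """The reference classification fixture: chr1 '+' gene, TSS 10 kb, TES 20 kb."""
    return eq.GeneModel(
        "gfix", "chr1", "+", 10_000, 20_000,
        exons=((10_000, 13_000), (14_000, 15_000), (18_000, 20_000)),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
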