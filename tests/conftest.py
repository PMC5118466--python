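import numpy as np
import pytest

from inseqtools.reference import (
    GeneModel,
    ReferenceIndex,
    Replicon,
    flag_duplicated_genes,
    site_assayability,
)
from inseqtools.simulate import SimConfig, simulate_genome


def random_genome(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_index(rng):
    """Single unique-sequence chromosome with three genes; all sites assayable."""
    seq = random_genome(rng, 600)
    rep = Replicon("chrom", seq, "chromosome")
    genes = [
        GeneModel("g1", "chrom", 50, 200, "+", product="hypothetical protein"),
        GeneModel("g2", "chrom", 220, 400, "-", product="ABC transporter"),
        GeneModel("g3", "chrom", 420, 560, "+", product="conserved hypothetical protein"),
    ]
    index = ReferenceIndex([rep], genes)
    site_assayability(index)
    flag_duplicated_genes(index)
    return index


@pytest.fixture(scope="session")
def default_sim():
    """Simulator genome + truth at the default study conditions (200 genes)."""
    config = SimConfig()
    index, truth = simulate_genome(config, seed=7)
    site_assayability(index, config.tag_len)
    flag_duplicated_genes(index)
    return config, index, truth
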