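import numpy as np
import pytest

from smdscan import io_formats as io
from smdscan import synthetic_data as sd


@pytest.fixture(scope="session")
def default_config():
    return sd.GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def toy_world(default_config):
    """One generated genome/annotation/truth shared across read-only tests."""
    genome, genes, truth = sd.generate_genome(default_config)
    return genome, genes, truth


@pytest.fixture(scope="session")
def bdf2():
    transcript, gene, truth = sd.bdf2_like_fixture()
    genome = io.GenomeSequence({gene.chrom: transcript})
    return transcript, gene, truth, genome


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_sequence(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
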