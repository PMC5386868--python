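import numpy as np
import pytest

from norinherit.genome import Chromosome, GenomeModel


@pytest.fixture
def arabidopsis():
    return GenomeModel.arabidopsis()


@pytest.fixture
def compact():
    return GenomeModel.compact()


@pytest.fixture
def mini_genome():
    """Two-chromosome genome (NOR2 + baseline chromosome) for fast checks."""
    return GenomeModel(
        chromosomes=[
            Chromosome("Chr2", 1_000_000, 50.0),
            Chromosome("Chr3", 1_000_000, 50.0),
        ],
        window_size_bp=100_000,
        nor_positions={"NOR2": ("Chr2", 0)},
        baseline_region=("Chr3", 0, 1_000_000),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
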