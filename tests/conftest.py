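import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from indelgwas.syndata import generate_genome, CrossDesign


@pytest.fixture(scope="session")
def small_genome():
    """1 chromosome x 100 kb with 5 genes."""
    return generate_genome(1, 100_000, 5, seed=7)


@pytest.fixture(scope="session")
def empty_genome():
    """2 chromosomes, no genes."""
    return generate_genome(2, 50_000, 0, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def demo_design():
    return CrossDesign(
        backcrosses=[("BC1_LD", "LD", 40), ("BC1_DU", "DU", 40), ("BC1_PI", "PI", 40)]
    )
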