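import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles imports

from brcaloh import load_genome_build
from brcaloh.simulate import SimulationParams


@pytest.fixture(scope="session")
def mini_genome():
    return load_genome_build("mini-test")


@pytest.fixture(scope="session")
def hg19():
    return load_genome_build("hg19")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def params():
    return SimulationParams(seed=11)
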