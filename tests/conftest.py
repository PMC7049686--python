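import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from diffcnn.synthetic import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small multi-tissue dataset (30 regions per class, variable lengths)
    shared by the I/O and training tests."""
    cfg = SimulationConfig(n_regions_per_class=30, region_length_range=(200, 240),
                           seed=3)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
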