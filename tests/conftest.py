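import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from halonitro.synthetic_data import (
    SimulationConfig,
    generate_community,
    generate_reference_panel,
)


@pytest.fixture(scope="session")
def panel():
    return generate_reference_panel(seed=11)


@pytest.fixture(scope="session")
def small_community():
    """Twelve-species, two-family community with strong identity contrast."""
    config = SimulationConfig(
        family_spec=[
            ("FamA", 8, {"non": 0.25, "partial": 0.5, "complete": 0.25}),
            ("FamB", 4, {"non": 0.25, "partial": 0.5, "complete": 0.25}),
        ],
        identity_true=0.85,
        identity_decoy=0.30,
        p_no_genome=0.0,
        seed=202,
    )
    return generate_community(config)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
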