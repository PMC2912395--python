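import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from methclass import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact seeded study exercising every downstream stage."""
    cfg = SimulationConfig(
        n_samples=80,
        n_loci=200,
        n_classes=3,
        class_mixing=(0.5, 0.3, 0.2),
        class_separation=1.5,
        n_x_loci=20,
        n_failing_loci=6,
        missing_rate=0.02,
        seed=11,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def study_scale_study():
    """The generator at its default (study-design) conditions."""
    return simulate_study(SimulationConfig(seed=7))
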