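import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from syntegene.pipeline import CladeInputs
from syntegene.simdata import PlantedEvent, SimConfig, simulate_clade


@pytest.fixture(scope="session")
def small_clade():
    """Three-species clade, one hidden gene in spB: the minimal discovery
    scenario shared by several test modules."""
    cfg = SimConfig(
        seed=3,
        n_species=3,
        genes_per_chromosome=20,
        events=[
            PlantedEvent(kind="hide_annotation", species="spB", aa_identity=0.55)
        ],
    )
    return simulate_clade(cfg)


@pytest.fixture(scope="session")
def small_inputs(small_clade):
    b = small_clade
    return CladeInputs(b.genomes, b.annotations, b.pillars, b.order)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
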