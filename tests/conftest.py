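import numpy as np
import pytest

from penmir import catalog
from penmir.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale experiment: 3 libraries, shallow depth, few miRNAs."""
    return SimulationConfig(
        seed=11,
        n_transcripts=12,
        n_conserved=3,
        n_novel=3,
        n_targets=4,
        libraries=(
            ("vitro_a", "in_vitro", 3000),
            ("vitro_b", "in_vitro", 3000),
            ("field_a", "field", 3000),
        ),
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def reference_catalog():
    return catalog.load_known_mirnas()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
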