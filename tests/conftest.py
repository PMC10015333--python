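import numpy as np
import pytest

from riskgrid.synthetic_data import SyntheticScenario, generate

SMALL_COUNTS = {
    "birds": 6,
    "mammals": 5,
    "reptiles": 4,
    "amphibians": 4,
    "arthropods": 6,
    "molluscs": 4,
    "vascular_plants": 12,
    "mosses": 3,
    "lichens": 3,
}


@pytest.fixture(scope="session")
def small_scenario():
    return SyntheticScenario(seed=11, group_counts=dict(SMALL_COUNTS), n_global_only=6)


@pytest.fixture(scope="session")
def small_bundle(small_scenario):
    return generate(small_scenario)


@pytest.fixture(scope="session")
def small_layers(small_bundle):
    return small_bundle[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
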