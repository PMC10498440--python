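import pytest

import polyforge as pf
from polyforge.fixtures import FAMILY_SIZES


@pytest.fixture(scope="session")
def registry():
    return pf.load_registry()


@pytest.fixture(scope="session")
def toy_table(registry):
    """A seeded synthetic monomer set covering all 19 classes, classified."""
    toy = pf.generate_toy_monomer_set(1, {name: 3 for name in FAMILY_SIZES})
    return pf.screen_library(toy, registry)


@pytest.fixture(scope="session")
def toy_library(toy_table):
    return pf.generate_library(toy_table)
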