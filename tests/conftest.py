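import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import foodwebmsy as fw

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def motif_balanced():
    return fw.solve_mass_balance(fw.motif_foodweb())


@pytest.fixture(scope="session")
def motif_links(motif_balanced):
    return fw.init_arena_params(motif_balanced, 2.0)


@pytest.fixture(scope="session")
def temp_series():
    """Annual July-August forcing from the default warming scenario."""
    spec = fw.SynthesisSpec()
    monthly = fw.generate_temperature_series(spec, seed=99)
    return fw.build_temperature_forcing(monthly)


def two_group_web(v=None, Y_prey=2.0):
    """Producer-fed prey plus one predator; the hand-algebra workhorse."""
    from foodwebmsy.core import (CatchTable, DietMatrix, FoodWebModel,
                                 FunctionalGroup)
    groups = [
        FunctionalGroup("plants", "producer", B=100.0, PB=50.0),
        FunctionalGroup("waste", "detritus", B=10.0),
        FunctionalGroup("prey", "consumer", B=10.0, PB=2.0, QB=8.0),
        FunctionalGroup("pred", "consumer", B=1.0, PB=0.5, QB=5.0),
    ]
    diet = DietMatrix.from_dict(
        {"prey": {"plants": 1.0}, "pred": {"prey": 1.0}},
        [g.name for g in groups])
    return FoodWebModel(groups, diet, CatchTable({"prey": Y_prey}))


@pytest.fixture()
def two_group_balanced():
    return fw.solve_mass_balance(two_group_web())


def isolated_target_web():
    """A fished stock with no trophic links to the dynamic subweb."""
    from foodwebmsy.core import (CatchTable, DietMatrix, FoodWebModel,
                                 FunctionalGroup)
    groups = [
        FunctionalGroup("stock", "producer", B=1.0, PB=1.0),
        FunctionalGroup("plants", "producer", B=50.0, PB=30.0),
        FunctionalGroup("waste", "detritus", B=10.0),
        FunctionalGroup("grazer", "consumer", B=5.0, PB=2.0, QB=10.0),
    ]
    diet = DietMatrix.from_dict({"grazer": {"plants": 1.0}},
                                [g.name for g in groups])
    return FoodWebModel(groups, diet, CatchTable({"stock": 0.2, "grazer": 0.5}))


@pytest.fixture()
def isolated_balanced():
    return fw.solve_mass_balance(isolated_target_web())
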