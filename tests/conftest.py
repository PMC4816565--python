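import numpy as np
import pytest

from solvshell.structure_io import classify_species
from solvshell.synthetic import (
    SolvationProfileSpec,
    SpeciesDensity,
    MOLAR_TO_PER_A3,
    WATER_OXYGEN_DENSITY,
    make_toy_protein,
    solvate_with_profile,
)


@pytest.fixture(scope="session")
def helix20():
    return make_toy_protein(20, "helix")


@pytest.fixture(scope="session")
def ternary_spec():
    """Uniform ternary composition: water + 2 M DMF + 0.5 M trehalose."""
    return SolvationProfileSpec(
        water=SpeciesDensity(WATER_OXYGEN_DENSITY, 1.0),
        dmf=SpeciesDensity(2.0 * MOLAR_TO_PER_A3, 1.0),
        trehalose=SpeciesDensity(0.5 * MOLAR_TO_PER_A3, 1.0),
        seed=42,
    )


@pytest.fixture(scope="session")
def uniform_box(helix20, ternary_spec):
    system = solvate_with_profile(helix20, ternary_spec)
    return system, classify_species(system)
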