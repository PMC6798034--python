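import numpy as np
import pytest

from enmremd import enm as enm_mod
from enmremd.fixtures import ToyDimerParams, make_toy_dimer


class ArrayStructure:
    """Bare coordinate/mass holder for small ad-hoc elastic networks."""

    def __init__(self, coords, mass=110.0):
        self.coords = np.asarray(coords, dtype=float)
        self.masses = np.full(len(self.coords), float(mass))


@pytest.fixture(scope="session")
def toy():
    """Default toy dimer (80 beads, 4 domains of 20) with its partition."""
    return make_toy_dimer(ToyDimerParams())


@pytest.fixture(scope="session")
def toy_model(toy):
    """Computed-mode elastic network of the default toy dimer."""
    structure, _ = toy
    model = enm_mod.build_network(structure)
    return enm_mod.compute_modes(model)


@pytest.fixture
def array_structure():
    return ArrayStructure
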