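import numpy as np
import pytest

from firesev import DiameterClassScheme, PatchStructure, Species, SpeciesAllometry


@pytest.fixture(scope="session")
def scheme():
    return DiameterClassScheme()


@pytest.fixture(scope="session")
def spruce_allometry():
    return SpeciesAllometry.for_species(Species.BLACK_SPRUCE)


@pytest.fixture(scope="session")
def pine_allometry():
    return SpeciesAllometry.for_species(Species.JACK_PINE)


def random_patch(rng: np.random.Generator, species=None) -> PatchStructure:
    """A valid random patch: non-empty integer counts in the 15 classes."""
    if species is None:
        species = (Species.BLACK_SPRUCE, Species.JACK_PINE)[rng.integers(0, 2)]
    counts = rng.integers(0, 400, size=15)
    if counts.sum() == 0:
        counts[rng.integers(0, 15)] = 1
    return PatchStructure(species=Species(species), counts=counts, region="A2")


@pytest.fixture
def rng():
    return np.random.default_rng(20160226)
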