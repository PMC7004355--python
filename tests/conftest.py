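import numpy as np
import pytest

from remotecat.simulate import gen_structure, ligand_moieties
from remotecat.structure import LigandMoiety, read_structure


@pytest.fixture(scope="session")
def toy_structure():
    """Default synthetic structure (3/2/1 layer plan) with its manifest."""
    pdb, manifest = gen_structure()
    return read_structure(pdb), manifest


@pytest.fixture(scope="session")
def toy_ligand(toy_structure):
    structure, _ = toy_structure
    return LigandMoiety("whole-ligand", structure.het_atoms())


@pytest.fixture(scope="session")
def toy_moieties(toy_structure):
    structure, manifest = toy_structure
    return ligand_moieties(structure, manifest)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
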