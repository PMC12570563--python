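import pytest

from rigidkit.fixtures import ideal_helix_pdb, toy_molecule_pdb
from rigidkit.interactions import InteractionConfig, build_molecular_graph
from rigidkit.pdbio import parse_pdb


@pytest.fixture(scope="session")
def helix_text():
    return ideal_helix_pdb(10)


@pytest.fixture(scope="session")
def helix_atoms(helix_text):
    return parse_pdb(helix_text)


@pytest.fixture(scope="session")
def helix_mol(helix_atoms):
    return build_molecular_graph(helix_atoms, InteractionConfig())


@pytest.fixture(scope="session")
def toy_mol():
    def make(kind):
        return build_molecular_graph(parse_pdb(toy_molecule_pdb(kind)), InteractionConfig())

    return make
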