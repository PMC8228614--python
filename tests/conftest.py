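import numpy as np
import pytest

from qsar3d.conformers import Molecule3D, embed_and_minimize
from qsar3d.dataset import load_pae_dataset
from qsar3d.pipeline import RunConfig, build_model


@pytest.fixture(scope="session")
def dataset():
    return load_pae_dataset()


@pytest.fixture(scope="session")
def dmp():
    return embed_and_minimize("COC(=O)c1ccccc1C(=O)OC", seed=42, abbrev="DMP")


@pytest.fixture(scope="session")
def dbp():
    return embed_and_minimize("CCCCOC(=O)c1ccccc1C(=O)OCCCC", seed=42, abbrev="DBP")


@pytest.fixture(scope="session")
def ld50_comfa_run():
    """Full pipeline on the 13-compound LD50 set (shared across tests)."""
    return build_model(RunConfig(endpoint="LD50", method="comfa"))


def make_toy_mol(elements, coords, charges=None, hydrophobic=None, donor=None,
                 acceptor=None, abbrev="toy"):
    """Molecule3D with explicit arrays; no RDKit handle needed for fields."""
    from rdkit import Chem

    n = len(elements)
    pt = Chem.GetPeriodicTable()
    return Molecule3D(
        abbrev=abbrev,
        smiles="",
        elements=list(elements),
        coords=np.asarray(coords, dtype=float),
        charges=np.zeros(n) if charges is None else np.asarray(charges, float),
        hydrophobic=np.zeros(n) if hydrophobic is None else np.asarray(hydrophobic, float),
        vdw_radius=np.array([pt.GetRvdw(pt.GetAtomicNumber(e)) for e in elements], float),
        donor=np.zeros(n, bool) if donor is None else np.asarray(donor, bool),
        acceptor=np.zeros(n, bool) if acceptor is None else np.asarray(acceptor, bool),
    )


@pytest.fixture
def toy_mol_factory():
    return make_toy_mol
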