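import numpy as np
import pytest

from chemscreen.molgraph import Atom, Molecule, assign_implicit_hydrogens


def make_molecule(elements, bonds, coords=None, charges=None, mol_id="test"):
    charges = charges or [0] * len(elements)
    atoms = [
        Atom(element=e, formal_charge=q,
             coords=None if coords is None else np.asarray(coords[i], dtype=float))
        for i, (e, q) in enumerate(zip(elements, charges))
    ]
    mol = Molecule(atoms=atoms, bonds=[(i, j, float(o)) for i, j, o in bonds], id=mol_id)
    assign_implicit_hydrogens(mol)
    return mol


@pytest.fixture
def methane():
    return make_molecule(["C"], [], coords=[[0.0, 0.0, 0.0]], mol_id="methane")


@pytest.fixture
def water():
    return make_molecule(["O"], [], mol_id="water")


@pytest.fixture
def ethane():
    return make_molecule(["C", "C"], [(0, 1, 1)],
                         coords=[[0, 0, 0], [1.54, 0, 0]], mol_id="ethane")


@pytest.fixture
def acetate():
    # CH3-C(=O)-O(-)
    return make_molecule(
        ["C", "C", "O", "O"],
        [(0, 1, 1), (1, 2, 2), (1, 3, 1)],
        charges=[0, 0, 0, -1],
        mol_id="acetate",
    )


@pytest.fixture
def cyclohexane():
    coords = [
        [np.cos(2 * np.pi * k / 6), np.sin(2 * np.pi * k / 6), 0.0] for k in range(6)
    ]
    bonds = [(k, (k + 1) % 6, 1) for k in range(6)]
    return make_molecule(["C"] * 6, bonds, coords=coords, mol_id="ring")


@pytest.fixture
def small_library():
    """Deterministic 60-molecule synthetic library with coordinates."""
    from chemscreen.synthetic import FixtureSpec, generate_library

    return generate_library(FixtureSpec(n_compounds=60, seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
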