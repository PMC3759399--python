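"""Molecular graph data model and structure-file I/O.

A :class:`Molecule` is a light atom/bond graph with optional 3D coordinates.
It deliberately carries less state than an RDKit ``Mol``: descriptor
generation only needs elements, formal charges, bond orders, coordinates and
implicit-hydrogen counts.  SDF (V2000) records are parsed through RDKit; the
record splitting and the 2D-only convention (an all-zero coordinate block
means "no geometry") live here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np
from rdkit import Chem
from rdkit import RDLogger
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: sentinel for atom pairs in different connected components
UNREACHABLE = -1

AROMATIC_ORDER = 1.5

#: standard valences used to derive implicit hydrogen counts
DEFAULT_VALENCE = {
    "H": 1, "C": 4, "N": 3, "O": 2, "F": 1, "P": 3, "S": 2,
    "Cl": 1, "Br": 1, "I": 1, "B": 3, "Si": 4,
}


class MoleculeError(ValueError):
    """Malformed molecular graph."""


class UnsupportedDialectError(ValueError):
    """Structure record in a dialect this reader does not handle (e.g. V3000)."""


class NoGeometryError(ValueError):
    """A 3D operation was requested on a molecule without coordinates."""


@dataclass
class Atom:
    """Single atom: element symbol, formal charge (e), optional coordinates (Å)."""

    element: str
    formal_charge: int = 0
    coords: Optional[np.ndarray] = None
    n_implicit_h: int = 0

    def __post_init__(self) -> None:
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (3,):
                raise MoleculeError(f"coords must be a 3-vector, got {self.coords.shape}")


@dataclass
class Molecule:
    """Atom/bond graph with optional 3D coordinates.

    Bonds are ``(i, j, order)`` with ``order`` in {1, 2, 3, 1.5 (aromatic)}.
    The graph may be disconnected; :attr:`is_connected` flags that.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    id: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        norm_bonds: list[tuple[int, int, float]] = []
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise MoleculeError(f"bond ({i},{j}) endpoint out of range for {n} atoms")
            if i == j:
                raise MoleculeError(f"self-bond on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise MoleculeError(f"duplicate bond {key}")
            seen.add(key)
            norm_bonds.append((key[0], key[1], float(order)))
        self.bonds = norm_bonds
        with_coords = [a.coords is not None for a in self.atoms]
        if any(with_coords) and not all(with_coords):
            raise MoleculeError("coords must be all-present or all-absent")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def has_coords(self) -> bool:
        return bool(self.atoms) and self.atoms[0].coords is not None

    @property
    def net_formal_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    @property
    def is_connected(self) -> bool:
        if self.n_atoms <= 1:
            return True
        d = topological_distances(self)
        return not np.any(d == UNREACHABLE)

    def coords_array(self) -> np.ndarray:
        if not self.has_coords:
            raise NoGeometryError(f"molecule {self.id!r} has no 3D coordinates")
        return np.vstack([a.coords for a in self.atoms])

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        out = []
        for a, b, order in self.bonds:
            if a == i:
                out.append((b, order))
            elif b == i:
                out.append((a, order))
        return out

    def bond_order_sum(self, i: int) -> float:
        return sum(order for _, order in self.neighbors(i))


def implicit_hydrogens(element: str, formal_charge: int, bond_order_sum: float) -> int:
    """Implicit H count from standard valence, adjusted by formal charge.

    The effective valence is ``default + charge`` which covers the common
    organic ions (N+ 4, O- 1, C- 3, O+ 3).
    """
    valence = DEFAULT_VALENCE.get(element)
    if valence is None:
        return 0
    effective = max(0, valence + formal_charge)
    return max(0, int(round(effective - bond_order_sum)))


def assign_implicit_hydrogens(mol: Molecule) -> None:
    """Recompute ``n_implicit_h`` for every atom in place."""
    for i, atom in enumerate(mol.atoms):
        atom.n_implicit_h = implicit_hydrogens(
            atom.element, atom.formal_charge, mol.bond_order_sum(i)
        )


def topological_distances(mol: Molecule) -> np.ndarray:
    """Shortest-path bond-count matrix; :data:`UNREACHABLE` for disconnected pairs."""
    n = mol.n_atoms
    if n == 0:
        return np.zeros((0, 0), dtype=int)
    rows = [b[0] for b in mol.bonds] + [b[1] for b in mol.bonds]
    cols = [b[1] for b in mol.bonds] + [b[0] for b in mol.bonds]
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = shortest_path(graph, method="D", unweighted=True, directed=False)
    out = np.full((n, n), UNREACHABLE, dtype=int)
    finite = np.isfinite(dist)
    out[finite] = dist[finite].astype(int)
    return out


# ---------------------------------------------------------------------------
# SDF I/O
# ---------------------------------------------------------------------------

_BOND_ORDER_FROM_RDKIT = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: AROMATIC_ORDER,
}
_BOND_TYPE_TO_RDKIT = {
    1.0: Chem.BondType.SINGLE,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
    AROMATIC_ORDER: Chem.BondType.AROMATIC,
}


def _from_rdkit(rdmol: Chem.Mol, mol_id: str) -> Molecule:
    conf = rdmol.GetConformer() if rdmol.GetNumConformers() else None
    coords = None
    if conf is not None:
        pts = conf.GetPositions()
        if np.any(np.abs(pts) > 1e-8):  # all-zero block = no 3D information
            coords = pts
    atoms = []
    for idx, a in enumerate(rdmol.GetAtoms()):
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                coords=None if coords is None else coords[idx],
            )
        )
    bonds = []
    for b in rdmol.GetBonds():
        order = _BOND_ORDER_FROM_RDKIT.get(b.GetBondType())
        if order is None:
            order = float(b.GetBondTypeAsDouble())
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    mol = Molecule(atoms=atoms, bonds=bonds, id=mol_id)
    assign_implicit_hydrogens(mol)
    return mol


def _iter_sdf_records(text: str) -> Iterable[str]:
    block: list[str] = []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            if any(l.strip() for l in block):
                yield "\n".join(block) + "\n"
            block = []
        else:
            block.append(line)
    if any(l.strip() for l in block):
        yield "\n".join(block) + "\n"


def read_sdf(source: Union[str, Path, TextIO]) -> list[Molecule]:
    """Read an SDF (V2000) file or text stream into :class:`Molecule` records.

    Records that fail to parse are skipped with a logged warning; a V3000
    record raises :class:`UnsupportedDialectError`.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        path = Path(source)
        try:
            text = path.read_text()
        except OSError as exc:
            raise IOError(f"cannot read SDF source {source!r}: {exc}") from exc
    molecules: list[Molecule] = []
    n_failed = 0
    for rec_idx, record in enumerate(_iter_sdf_records(text)):
        lines = record.splitlines()
        counts_line = lines[3] if len(lines) > 3 else ""
        if "V3000" in counts_line:
            name = lines[0].strip() or f"record {rec_idx}"
            raise UnsupportedDialectError(f"V3000 record not supported: {name}")
        rdmol = Chem.MolFromMolBlock(record, sanitize=False, removeHs=False)
        if rdmol is None:
            n_failed += 1
            logger.warning("skipping unparseable SDF record %d (%r)", rec_idx, lines[0][:40])
            continue
        mol_id = lines[0].strip() or f"MOL{rec_idx:05d}"
        try:
            molecules.append(_from_rdkit(rdmol, mol_id))
        except MoleculeError as exc:
            n_failed += 1
            logger.warning("skipping invalid SDF record %d: %s", rec_idx, exc)
    if n_failed:
        logger.warning("read_sdf: %d record(s) skipped", n_failed)
    return molecules


def to_rdkit(mol: Molecule, sanitize: bool = True) -> Chem.Mol:
    """Convert to an RDKit ``Mol`` (used for delegated scalar descriptors)."""
    rw = Chem.RWMol()
    for atom in mol.atoms:
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(atom.formal_charge)
        rw.AddAtom(a)
    for i, j, order in mol.bonds:
        bt = _BOND_TYPE_TO_RDKIT.get(order)
        if bt is None:
            raise MoleculeError(f"cannot express bond order {order} in SDF")
        rw.AddBond(i, j, bt)
        if bt is Chem.BondType.AROMATIC:
            rw.GetAtomWithIdx(i).SetIsAromatic(True)
            rw.GetAtomWithIdx(j).SetIsAromatic(True)
            rw.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
    out = rw.GetMol()
    if mol.has_coords:
        conf = Chem.Conformer(mol.n_atoms)
        for idx, atom in enumerate(mol.atoms):
            conf.SetAtomPosition(idx, tuple(float(c) for c in atom.coords))
        out.AddConformer(conf)
    if sanitize:
        Chem.SanitizeMol(out)
    out.SetProp("_Name", mol.id)
    return out


def write_sdf(molecules: Sequence[Molecule], target: Union[str, Path, TextIO]) -> None:
    """Write molecules as an SDF (V2000) file; 2D-only molecules get a zero block."""
    blocks = []
    for mol in molecules:
        rdmol = to_rdkit(mol, sanitize=False)
        if not mol.has_coords:
            conf = Chem.Conformer(mol.n_atoms)
            for idx in range(mol.n_atoms):
                conf.SetAtomPosition(idx, (0.0, 0.0, 0.0))
            rdmol.AddConformer(conf)
        block = Chem.MolToMolBlock(rdmol, kekulize=False)
        blocks.append(block + "$$$$\n")
    text = "".join(blocks)
    if hasattr(target, "write"):
        target.write(text)
    else:
        Path(target).write_text(text)
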