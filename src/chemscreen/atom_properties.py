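"""Per-atom chemical properties for descriptor generation.

Nine properties are computed per heavy atom, plus the van der Waals surface
area used as an optional weight:

* atom identity (element number)
* sigma, pi and total partial charge (e) — damped partial-equalization
  (PEOE) iteration, six rounds with damping (1/2)^k
* sigma, pi and lone-pair orbital electronegativity (eV), evaluated at the
  converged charges
* effective polarizability (Å^3) — distance-damped sum of atomic
  contributions
* "VC2003" charge — substituted by the total PEOE charge (the original
  parameterization is not available); kept as a separate column so the
  descriptor catalog retains its nine-property layout

Property iterations run on an internally hydrogen-expanded graph; charges of
implicit hydrogens are folded back into their parent heavy atom so the
per-atom table sums to the molecular net formal charge.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from rdkit import Chem

from .molgraph import AROMATIC_ORDER, Molecule, topological_distances

PROPERTY_IDS = (
    "atom_identity",
    "sigma_charge",
    "pi_charge",
    "total_charge",
    "sigma_electronegativity",
    "pi_electronegativity",
    "lone_pair_electronegativity",
    "effective_polarizability",
    "vc2003_charge",
)

VDW_SURFACE_AREA = "vdw_surface_area"

#: damping base of the charge-transfer iteration
PEOE_DAMPING = 0.5
PEOE_ITERATIONS = 6
#: per-bond attenuation of the polarizability contribution sum
POLARIZABILITY_DAMPING = 0.5


class UnsupportedElementError(KeyError):
    """Element missing from the parameter table (never silently zero)."""


@lru_cache(maxsize=1)
def load_parameter_table() -> dict:
    with resources.files("chemscreen").joinpath("data/peoe_params.json").open() as fh:
        return json.load(fh)


def hybridization(mol: Molecule) -> list[str]:
    """Assign sp/sp2/sp3 from bond orders (triple or cumulated double → sp)."""
    out = []
    for i in range(mol.n_atoms):
        orders = [o for _, o in mol.neighbors(i)]
        n_double = sum(1 for o in orders if o == 2.0)
        if any(o == 3.0 for o in orders) or n_double >= 2:
            out.append("sp")
        elif n_double == 1 or any(o == AROMATIC_ORDER for o in orders):
            out.append("sp2")
        else:
            out.append("sp3")
    return out


def _sigma_params(element: str, hyb: str, table: dict) -> tuple[float, float, float]:
    per_elem = table["sigma"].get(element)
    if per_elem is None:
        raise UnsupportedElementError(
            f"element {element!r} not in the PEOE parameter table"
        )
    if element == "H":
        return tuple(per_elem["s"])
    params = per_elem.get(hyb) or per_elem.get("sp3") or next(iter(per_elem.values()))
    return tuple(params)


def _optional_params(element: str, hyb: str, block: dict) -> Optional[tuple[float, float, float]]:
    per_elem = block.get(element)
    if per_elem is None:
        return None
    params = per_elem.get(hyb)
    if params is None:
        params = per_elem.get("sp3") if hyb == "sp" else None
    return None if params is None else tuple(params)


def _chi(params: np.ndarray, q: np.ndarray) -> np.ndarray:
    return params[:, 0] + params[:, 1] * q + params[:, 2] * q * q


class _ExpandedGraph:
    """Heavy atoms followed by one pseudo-atom per implicit hydrogen."""

    def __init__(self, mol: Molecule):
        self.mol = mol
        self.n_heavy = mol.n_atoms
        elements = [a.element for a in mol.atoms]
        charges = [float(a.formal_charge) for a in mol.atoms]
        bonds = [(i, j, o) for i, j, o in mol.bonds]
        self.h_parent: list[int] = []
        for i, atom in enumerate(mol.atoms):
            for _ in range(atom.n_implicit_h):
                idx = len(elements)
                elements.append("H")
                charges.append(0.0)
                bonds.append((i, idx, 1.0))
                self.h_parent.append(i)
        self.elements = elements
        self.initial_charges = np.array(charges)
        self.bonds = bonds
        self.n_total = len(elements)

    def fold(self, values: np.ndarray) -> np.ndarray:
        """Sum hydrogen values into their parent heavy atom."""
        out = values[: self.n_heavy].copy()
        for h_idx, parent in enumerate(self.h_parent):
            out[parent] += values[self.n_heavy + h_idx]
        return out


def _peoe(graph: _ExpandedGraph, params: np.ndarray, cation_chi: np.ndarray,
          bonds: list[tuple[int, int]], q0: np.ndarray,
          n_iter: int = PEOE_ITERATIONS) -> np.ndarray:
    """Damped partial-equalization charge iteration over the given bonds."""
    q = q0.copy()
    if not bonds:
        return q
    bi = np.array([b[0] for b in bonds])
    bj = np.array([b[1] for b in bonds])
    for k in range(1, n_iter + 1):
        damp = PEOE_DAMPING ** k
        chi = _chi(params, q)
        chi_i, chi_j = chi[bi], chi[bj]
        # electrons flow toward the more electronegative atom; the donor's
        # cation electronegativity normalizes the transfer
        donor_is_i = chi_j > chi_i
        norm = np.where(donor_is_i, cation_chi[bi], cation_chi[bj])
        dq = (chi_j - chi_i) / norm * damp
        np.add.at(q, bi, dq)
        np.add.at(q, bj, -dq)
    return q


def compute_atom_property_table(mol: Molecule) -> pd.DataFrame:
    """All nine catalog properties plus VdW surface area, one row per atom."""
    table = load_parameter_table()
    graph = _ExpandedGraph(mol)
    hyb_heavy = hybridization(mol)
    hyb = hyb_heavy + ["s"] * (graph.n_total - graph.n_heavy)

    sigma_params = np.array(
        [_sigma_params(el, h, table) for el, h in zip(graph.elements, hyb)]
    )
    cation_chi = sigma_params.sum(axis=1)
    cation_chi[np.array(graph.elements) == "H"] = table["hydrogen_cation_chi"]

    all_bonds = [(i, j) for i, j, _ in graph.bonds]
    q_sigma = _peoe(graph, sigma_params, cation_chi, all_bonds, graph.initial_charges)

    # pi system: atoms with pi parameters joined by multiple/aromatic bonds
    pi_params_list = [_optional_params(el, h, table["pi"]) for el, h in zip(graph.elements, hyb)]
    pi_bonds = [
        (i, j)
        for i, j, o in graph.bonds
        if o > 1.0 and pi_params_list[i] is not None and pi_params_list[j] is not None
    ]
    pi_params = np.array(
        [p if p is not None else (0.0, 0.0, 0.0) for p in pi_params_list]
    )
    pi_cation = np.where(pi_params.sum(axis=1) > 0, pi_params.sum(axis=1), 1.0)
    q_pi = _peoe(graph, pi_params, pi_cation, pi_bonds, np.zeros(graph.n_total))

    q_total = q_sigma + q_pi

    sigma_en = _chi(sigma_params, q_total)
    pi_en = np.where(pi_params.sum(axis=1) > 0, _chi(pi_params, q_total), 0.0)
    lp_params_list = [
        _optional_params(el, h, table["lone_pair"]) for el, h in zip(graph.elements, hyb)
    ]
    lp_params = np.array(
        [p if p is not None else (0.0, 0.0, 0.0) for p in lp_params_list]
    )
    lp_en = np.where(lp_params.sum(axis=1) > 0, _chi(lp_params, q_total), 0.0)

    alpha = effective_polarizability(mol)
    vdw = vdw_surface_areas(mol)

    heavy = slice(0, graph.n_heavy)
    pt = Chem.GetPeriodicTable()
    frame = pd.DataFrame(
        {
            "atom_identity": [
                float(pt.GetAtomicNumber(a.element)) for a in mol.atoms
            ],
            "sigma_charge": graph.fold(q_sigma),
            "pi_charge": graph.fold(q_pi),
            "total_charge": graph.fold(q_total),
            "sigma_electronegativity": sigma_en[heavy],
            "pi_electronegativity": pi_en[heavy],
            "lone_pair_electronegativity": lp_en[heavy],
            "effective_polarizability": alpha,
            "vc2003_charge": graph.fold(q_total),  # substitute, see module docstring
            VDW_SURFACE_AREA: vdw,
        }
    )
    return frame


def compute_atom_properties(mol: Molecule, property_id: str) -> np.ndarray:
    """One of the nine catalog properties (or VdW surface area) per atom."""
    if property_id not in PROPERTY_IDS and property_id != VDW_SURFACE_AREA:
        raise ValueError(f"unknown atom property {property_id!r}")
    return compute_atom_property_table(mol)[property_id].to_numpy()


def effective_polarizability(mol: Molecule) -> np.ndarray:
    """Distance-damped sum of atomic polarizability contributions (Å^3).

    alpha_eff(i) = sum_j damp^d(i,j) * alpha_j over the hydrogen-expanded
    graph, with implicit hydrogens one bond beyond their parent.
    """
    table = load_parameter_table()
    alpha_table = table["polarizability"]
    n = mol.n_atoms
    if n == 0:
        return np.zeros(0)
    try:
        alpha_heavy = np.array([alpha_table[a.element] for a in mol.atoms])
    except KeyError as exc:
        raise UnsupportedElementError(
            f"element {exc.args[0]!r} has no polarizability parameter"
        ) from exc
    alpha_h = alpha_table["H"]
    n_h = np.array([a.n_implicit_h for a in mol.atoms], dtype=float)
    dist = topological_distances(mol).astype(float)
    reach = dist >= 0
    damp = np.where(reach, POLARIZABILITY_DAMPING ** np.where(reach, dist, 0), 0.0)
    out = damp @ alpha_heavy
    # implicit hydrogens on atom j sit at distance d(i,j)+1 from atom i
    out += (damp * POLARIZABILITY_DAMPING) @ (n_h * alpha_h)
    return out


def vdw_surface_areas(mol: Molecule) -> np.ndarray:
    """Exposed van der Waals sphere area per atom (Å^2).

    Sphere area minus spherical-cap overlaps with bonded neighbours
    (including implicit hydrogens).  Bond lengths come from coordinates when
    present, otherwise from covalent-radius sums.
    """
    table = load_parameter_table()
    cov = table["covalent_radius"]
    pt = Chem.GetPeriodicTable()

    def rvdw(element: str) -> float:
        r = pt.GetRvdw(pt.GetAtomicNumber(element))
        if r <= 0:
            raise UnsupportedElementError(f"no VdW radius for element {element!r}")
        return r

    def rcov(element: str) -> float:
        try:
            return cov[element]
        except KeyError as exc:
            raise UnsupportedElementError(
                f"no covalent radius for element {element!r}"
            ) from exc

    coords = mol.coords_array() if mol.has_coords else None
    out = np.zeros(mol.n_atoms)
    for i, atom in enumerate(mol.atoms):
        r_i = rvdw(atom.element)
        area = 4.0 * np.pi * r_i**2
        neighbours: list[tuple[str, float]] = []
        for j, _ in mol.neighbors(i):
            if coords is not None:
                d = float(np.linalg.norm(coords[i] - coords[j]))
            else:
                d = rcov(atom.element) + rcov(mol.atoms[j].element)
            neighbours.append((mol.atoms[j].element, d))
        d_h = rcov(atom.element) + rcov("H")
        neighbours.extend([("H", d_h)] * atom.n_implicit_h)
        for elem_j, d in neighbours:
            r_j = rvdw(elem_j)
            if d <= 1e-6:
                continue
            # height of the cap of sphere i buried inside sphere j
            h = r_i - (d * d + r_i * r_i - r_j * r_j) / (2.0 * d)
            h = min(max(h, 0.0), 2.0 * r_i)
            area -= 2.0 * np.pi * r_i * h
        out[i] = max(area, 0.0)
    return out
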