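"""Deterministic synthetic molecule libraries and assay tables.

Every pipeline stage is testable without external downloads.  The generator
emulates the structure of a curated HTS campaign: a library of small
valence-valid organic molecules (random trees over a C/N/O/S/halogen
alphabet with template 3D geometry), an extreme class imbalance (1 active
per 100 compounds by default), actives with potencies in the 0.1–25 µM
range, inactives at 1 mM, and multi-assay outcome tables with planted
overlaps for exercising the curation set algebra.

The default activity rule thresholds the molecular-weight scalar, so
exactly one descriptor group carries the signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .activity import ActivityRecord, AssayOutcomeTable, CurationRecipe
from .descriptors import scalar_descriptors
from .molgraph import Atom, Molecule, assign_implicit_hydrogens, write_sdf

BOND_LENGTH = 1.54  # Å, template geometry
MIN_ATOM_SEPARATION = 1.0  # Å

#: weighted fragment alphabet: mostly carbon with polar/halogen decoration
DEFAULT_ALPHABET = ("C", "C", "C", "C", "C", "N", "O", "O", "S", "F", "Cl")

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1, "I": 1}


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic campaign."""

    n_compounds: int = 5000
    seed: int = 0
    alphabet: Sequence[str] = DEFAULT_ALPHABET
    n_heavy_range: tuple[int, int] = (8, 18)
    activity_rule: str = "molecular_weight"
    noise: float = 0.0  # label-flip probability
    base_active_fraction: float = 0.01
    potency_range_um: tuple[float, float] = (0.1, 25.0)
    carbonyl_probability: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.base_active_fraction < 1:
            raise ValueError("base_active_fraction must be in (0, 1)")


def _rule_molecular_weight(mol: Molecule) -> float:
    return scalar_descriptors(mol)[0]


def _rule_polar_atom_count(mol: Molecule) -> float:
    return float(sum(1 for a in mol.atoms if a.element in ("N", "O")))


ACTIVITY_RULES: dict[str, Callable[[Molecule], float]] = {
    "molecular_weight": _rule_molecular_weight,
    "polar_atom_count": _rule_polar_atom_count,
}


def _place_atom(rng: np.random.Generator, coords: list[np.ndarray], parent: int) -> np.ndarray:
    """Template geometry: fixed bond length, direction rejected if it clashes."""
    base = coords[parent]
    best = None
    best_min_dist = -1.0
    for _ in range(60):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        candidate = base + BOND_LENGTH * v
        dmin = min(float(np.linalg.norm(candidate - c)) for c in coords)
        if dmin >= MIN_ATOM_SEPARATION:
            return candidate
        if dmin > best_min_dist:
            best_min_dist, best = dmin, candidate
    return best


def _random_molecule(rng: np.random.Generator, spec: FixtureSpec, mol_id: str) -> Molecule:
    n_heavy = int(rng.integers(spec.n_heavy_range[0], spec.n_heavy_range[1] + 1))
    elements = ["C"]  # seed atom is carbon so the tree can always grow
    parents: list[Optional[int]] = [None]
    bonds: list[tuple[int, int, float]] = []
    free_valence = [_VALENCE["C"]]
    coords = [np.zeros(3)]
    while len(elements) < n_heavy:
        open_sites = [i for i, fv in enumerate(free_valence) if fv >= 1]
        if not open_sites:
            break
        parent = int(rng.choice(open_sites))
        elem = str(rng.choice(spec.alphabet))
        idx = len(elements)
        order = 1.0
        if (
            elem == "O"
            and elements[parent] == "C"
            and free_valence[parent] >= 2
            and rng.random() < spec.carbonyl_probability
        ):
            order = 2.0
        elements.append(elem)
        parents.append(parent)
        bonds.append((parent, idx, order))
        free_valence[parent] -= int(order)
        free_valence.append(_VALENCE[elem] - int(order))
        coords.append(_place_atom(rng, coords, parent))
    atoms = [
        Atom(element=e, formal_charge=0, coords=c) for e, c in zip(elements, coords)
    ]
    mol = Molecule(atoms=atoms, bonds=bonds, id=mol_id)
    assign_implicit_hydrogens(mol)
    return mol


def generate_library(
    spec: FixtureSpec, sdf_path: Optional[Union[str, Path]] = None
) -> list[Molecule]:
    """Deterministic molecule library; optionally also written as SDF."""
    rng = np.random.default_rng(spec.seed)
    library = [
        _random_molecule(rng, spec, f"SYN{i:05d}") for i in range(spec.n_compounds)
    ]
    if sdf_path is not None:
        write_sdf(library, sdf_path)
    return library


def generate_activity(
    library: Sequence[Molecule], spec: FixtureSpec
) -> list[ActivityRecord]:
    """Label the library by the activity rule, assign potencies, apply noise.

    Actives are the compounds whose rule value exceeds the
    (1 - base_active_fraction) quantile.  Potencies decrease (activity
    increases) with the rule margin, log-spaced across the configured range;
    noise flips labels at the stated rate (flipped-in actives get the
    representative 1 µM).
    """
    rule = ACTIVITY_RULES.get(spec.activity_rule)
    if rule is None:
        raise ValueError(f"unknown activity rule {spec.activity_rule!r}")
    rng = np.random.default_rng(spec.seed + 1)
    values = np.array([rule(mol) for mol in library])
    threshold = float(np.quantile(values, 1.0 - spec.base_active_fraction))
    is_active = values > threshold
    lo_um, hi_um = spec.potency_range_um
    records: list[ActivityRecord] = []
    # rank actives by margin: strongest margin → most potent (lowest IC50)
    potency_map: dict[int, float] = {}
    if is_active.any():
        active_idx = np.nonzero(is_active)[0]
        order = active_idx[np.argsort(-values[active_idx], kind="stable")]
        n_act = len(order)
        logs = np.linspace(np.log10(lo_um), np.log10(hi_um), num=max(n_act, 2))[:n_act]
        for rank, idx in enumerate(order):
            potency_map[int(idx)] = float(10.0 ** logs[rank] * 1e-6)
    flips = rng.random(len(library)) < spec.noise
    for i, mol in enumerate(library):
        active = bool(is_active[i]) ^ bool(flips[i])
        if active:
            potency = potency_map.get(i)  # flipped-in actives have no measurement
            records.append(
                ActivityRecord(
                    compound_id=mol.id, is_active=True,
                    raw_potency=potency, potency_kind="IC50" if potency else "none",
                )
            )
        else:
            records.append(ActivityRecord(compound_id=mol.id, is_active=False))
    return records


# ---------------------------------------------------------------------------
# Assay-table scenarios for the curation engine
# ---------------------------------------------------------------------------

@dataclass
class CurationScenario:
    tables: list[AssayOutcomeTable]
    recipe: CurationRecipe
    expected_active: set[str]
    expected_inactive: set[str]


def _ids(prefix: str, idx: Sequence[int]) -> list[str]:
    return [f"{prefix}{i:04d}" for i in idx]


def generate_assay_tables(scenario: str, seed: int = 0) -> CurationScenario:
    """Emit primary/confirmatory/counter tables with planted overlaps.

    Scenarios: ``subtract`` (confirmed minus one counter screen),
    ``union`` (two refined screens merged), ``kcnq2`` (confirmatory minus
    three counter screens), ``empty_counter`` (counter screens hit nothing).
    """
    rng = np.random.default_rng(seed)
    pool = _ids("CID", range(200))
    primary_active = set(rng.choice(pool, size=40, replace=False).tolist())
    primary_inactive = set(pool) - primary_active

    def table(aid: str, active: set[str], inactive: set[str]) -> AssayOutcomeTable:
        outcomes = {cid: "active" for cid in active}
        outcomes.update({cid: "inactive" for cid in inactive})
        return AssayOutcomeTable(assay_id=aid, outcomes=outcomes)

    primary = table("100", primary_active, primary_inactive)
    confirmed = set(sorted(primary_active)[:30])

    if scenario == "subtract":
        counter_hits = set(sorted(confirmed)[:3])
        tables = [
            primary,
            table("200", confirmed, primary_active - confirmed),
            table("300", counter_hits, confirmed - counter_hits),
        ]
        recipe = CurationRecipe(
            said="toy-subtract",
            expression={"op": "subtract", "args": [
                {"assay": "200", "set": "active"}, {"assay": "300", "set": "active"}]},
            inactive_source=["100"],
        )
        expected_active = confirmed - counter_hits
    elif scenario == "union":
        set_a = set(sorted(confirmed)[:18])
        set_b = set(sorted(confirmed)[12:])  # overlap planted
        tables = [primary, table("210", set_a, confirmed - set_a),
                  table("220", set_b, confirmed - set_b)]
        recipe = CurationRecipe(
            said="toy-union",
            expression={"op": "union", "args": [
                {"assay": "210", "set": "active"}, {"assay": "220", "set": "active"}]},
            inactive_source=["100"],
        )
        expected_active = set_a | set_b
    elif scenario == "kcnq2":
        counters = [set(rng.choice(sorted(confirmed), size=4, replace=False).tolist())
                    for _ in range(3)]
        tables = [primary, table("2287", confirmed, primary_active - confirmed)]
        for aid, hits in zip(("2282", "2283", "2558"), counters):
            tables.append(table(aid, hits, confirmed - hits))
        recipe = CurationRecipe(
            said="toy-kcnq2",
            expression={"op": "subtract", "args": [
                {"assay": "2287", "set": "active"},
                {"op": "union", "args": [
                    {"assay": "2282", "set": "active"},
                    {"assay": "2283", "set": "active"},
                    {"assay": "2558", "set": "active"}]}]},
            inactive_source=["100"],
        )
        expected_active = confirmed - (counters[0] | counters[1] | counters[2])
    elif scenario == "empty_counter":
        tables = [primary, table("200", confirmed, primary_active - confirmed),
                  table("300", set(), confirmed)]
        recipe = CurationRecipe(
            said="toy-empty-counter",
            expression={"op": "subtract", "args": [
                {"assay": "200", "set": "active"}, {"assay": "300", "set": "active"}]},
            inactive_source=["100"],
        )
        expected_active = confirmed
    else:
        raise ValueError(f"unknown curation scenario {scenario!r}")
    expected_inactive = primary_inactive - expected_active
    return CurationScenario(
        tables=tables, recipe=recipe,
        expected_active=expected_active, expected_inactive=expected_inactive,
    )
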