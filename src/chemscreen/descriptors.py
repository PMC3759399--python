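"""Fixed-length molecular descriptor vectors.

Three encoding functions turn a per-atom property vector into a
transformation-invariant fingerprint:

* 2D autocorrelation — sum of property products over atom pairs binned by
  topological (bond-count) distance, Moreau–Broto form; bin 0 holds the
  self-pair terms p_i^2.
* 3D autocorrelation — the same binned on Euclidean distance.
* Radial distribution function — Gaussian-smoothed pair-product density
  g(r_k) = sum_{i<j} p_i p_j exp(-B (r_k - d_ij)^2).

The default catalog pairs each of the nine atom properties with each
encoder, unweighted and weighted by the per-atom van der Waals surface area,
plus six scalar descriptors: 6 + 9 x 2 x (11 + 12 + 48) = 1,284 values in 60
groups.  The exact bin counts are configuration-driven.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .atom_properties import (
    PROPERTY_IDS,
    VDW_SURFACE_AREA,
    compute_atom_property_table,
)
from .molgraph import Molecule, NoGeometryError, UNREACHABLE, to_rdkit, topological_distances

logger = logging.getLogger(__name__)

SCALAR_NAMES = ("weight", "hbd", "hba", "logp", "charge", "tpsa")

DEFAULT_AC2D_BINS = 11
DEFAULT_AC3D_BINS = 12
DEFAULT_AC3D_BIN_WIDTH = 1.0  # Å
DEFAULT_RDF_BINS = 48
DEFAULT_RDF_R0 = 0.1  # Å
DEFAULT_RDF_STEP = 0.1  # Å
DEFAULT_RDF_B = 100.0  # Å^-2


@dataclass(frozen=True)
class DescriptorGroupSpec:
    """One named block of descriptor values, treated atomically in selection."""

    name: str
    kind: str  # scalar | ac2d | ac3d | rdf
    property_id: Optional[str] = None
    weighted: bool = False
    n_bins: int = 1
    bin_width: float = DEFAULT_AC3D_BIN_WIDTH
    rdf_b: float = DEFAULT_RDF_B

    def __post_init__(self):
        if self.kind not in ("scalar", "ac2d", "ac3d", "rdf"):
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.kind == "scalar" and (self.n_bins != 1 or self.weighted):
            raise ValueError("scalar groups are single, unweighted values")

    @property
    def needs_coords(self) -> bool:
        return self.kind in ("ac3d", "rdf")

    def column_names(self) -> list[str]:
        if self.n_bins == 1:
            return [self.name]
        return [f"{self.name}.{b}" for b in range(self.n_bins)]


@dataclass
class DescriptorConfig:
    """Ordered sequence of descriptor groups defining the feature layout."""

    groups: list[DescriptorGroupSpec]

    @property
    def total_length(self) -> int:
        return sum(g.n_bins for g in self.groups)

    @property
    def group_names(self) -> list[str]:
        return [g.name for g in self.groups]

    @classmethod
    def default(cls) -> "DescriptorConfig":
        groups = [DescriptorGroupSpec(name=n, kind="scalar") for n in SCALAR_NAMES]
        for prop in PROPERTY_IDS:
            for kind, n_bins in (
                ("ac2d", DEFAULT_AC2D_BINS),
                ("ac3d", DEFAULT_AC3D_BINS),
                ("rdf", DEFAULT_RDF_BINS),
            ):
                for weighted in (False, True):
                    suffix = "_w" if weighted else ""
                    groups.append(
                        DescriptorGroupSpec(
                            name=f"{kind}_{prop}{suffix}",
                            kind=kind,
                            property_id=prop,
                            weighted=weighted,
                            n_bins=n_bins,
                        )
                    )
        return cls(groups=groups)

    @classmethod
    def scalars_only(cls) -> "DescriptorConfig":
        return cls(groups=[DescriptorGroupSpec(name=n, kind="scalar") for n in SCALAR_NAMES])

    def to_json(self, path: Union[str, Path]) -> None:
        payload = [g.__dict__ for g in self.groups]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "DescriptorConfig":
        payload = json.loads(Path(path).read_text())
        return cls(groups=[DescriptorGroupSpec(**g) for g in payload])


@dataclass
class FeatureMatrix:
    """Compounds x descriptor values, with the column → group mapping."""

    frame: pd.DataFrame
    group_columns: dict[str, list[str]]

    @property
    def compound_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def group_names(self) -> list[str]:
        return list(self.group_columns)

    def values_for_groups(self, groups: Sequence[str]) -> np.ndarray:
        cols: list[str] = []
        for g in groups:
            cols.extend(self.group_columns[g])
        return self.frame[cols].to_numpy(dtype=float)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.frame.to_csv(path, index_label="compound_id")

    @classmethod
    def from_csv(cls, path: Union[str, Path],
                 config: Optional[DescriptorConfig] = None) -> "FeatureMatrix":
        frame = pd.read_csv(path, index_col="compound_id")
        frame.index = frame.index.astype(str)
        if config is None:
            config = DescriptorConfig.default()
        group_columns = {g.name: g.column_names() for g in config.groups}
        return cls(frame=frame, group_columns=group_columns)


# ---------------------------------------------------------------------------
# Scalar descriptors
# ---------------------------------------------------------------------------

def scalar_descriptors(mol: Molecule) -> tuple[float, float, float, float, float, float]:
    """(MW, HBD, HBA, logP, net formal charge, TPSA).

    HBD counts N/O atoms bearing at least one hydrogen, HBA counts N/O atoms;
    logP (Crippen) and TPSA (Ertl) are delegated to RDKit.
    """
    rdmol = to_rdkit(mol, sanitize=True)
    mw = Descriptors.MolWt(rdmol)
    hbd = 0
    hba = 0
    for i, atom in enumerate(mol.atoms):
        if atom.element in ("N", "O"):
            hba += 1
            has_h = atom.n_implicit_h > 0 or any(
                mol.atoms[j].element == "H" for j, _ in mol.neighbors(i)
            )
            if has_h:
                hbd += 1
    logp = Crippen.MolLogP(rdmol)
    tpsa = rdMolDescriptors.CalcTPSA(rdmol)
    return (mw, float(hbd), float(hba), logp, float(mol.net_formal_charge), tpsa)


# ---------------------------------------------------------------------------
# Encoders — each accepts a 1-D property vector or an (n_atoms, n_props)
# matrix and returns (n_bins,) or (n_bins, n_props) accordingly.
# ---------------------------------------------------------------------------

def _as_matrix(property_values: np.ndarray, n_atoms: int) -> tuple[np.ndarray, bool]:
    p = np.asarray(property_values, dtype=float)
    squeeze = p.ndim == 1
    if squeeze:
        p = p[:, None]
    if p.shape[0] != n_atoms:
        raise ValueError(f"property length {p.shape[0]} != atom count {n_atoms}")
    return p, squeeze


def autocorrelation_2d(
    mol: Molecule,
    property_values: np.ndarray,
    n_bins: int = DEFAULT_AC2D_BINS,
    distances: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Topological Moreau–Broto autocorrelation.

    Bin d sums p_i * p_j over unordered pairs at bond distance d; bin 0 holds
    the self-pairs p_i^2.  Unreachable pairs are ignored.
    """
    p, squeeze = _as_matrix(property_values, mol.n_atoms)
    if distances is None:
        distances = topological_distances(mol)
    out = np.zeros((n_bins, p.shape[1]))
    out[0] = (p * p).sum(axis=0)
    for d in range(1, n_bins):
        mask = np.triu(distances == d, k=1)
        if mask.any():
            ii, jj = np.nonzero(mask)
            out[d] = (p[ii] * p[jj]).sum(axis=0)
    return out[:, 0] if squeeze else out


def autocorrelation_3d(
    mol: Molecule,
    property_values: np.ndarray,
    n_bins: int = DEFAULT_AC3D_BINS,
    bin_width: float = DEFAULT_AC3D_BIN_WIDTH,
    coords: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Euclidean-distance autocorrelation; bin k covers [k*w, (k+1)*w).

    Self-pairs land in bin 0; pairs beyond the binned range are ignored.
    """
    p, squeeze = _as_matrix(property_values, mol.n_atoms)
    if coords is None:
        coords = mol.coords_array()
    out = np.zeros((n_bins, p.shape[1]))
    out[0] = (p * p).sum(axis=0)
    n = mol.n_atoms
    if n > 1:
        ii, jj = np.triu_indices(n, k=1)
        d = np.linalg.norm(coords[ii] - coords[jj], axis=1)
        bins = np.floor(d / bin_width).astype(int)
        keep = bins < n_bins
        prods = p[ii[keep]] * p[jj[keep]]
        np.add.at(out, bins[keep], prods)
    return out[:, 0] if squeeze else out


def rdf_grid(n_bins: int = DEFAULT_RDF_BINS, r0: float = DEFAULT_RDF_R0,
             step: float = DEFAULT_RDF_STEP) -> np.ndarray:
    return r0 + step * np.arange(n_bins)


def radial_distribution(
    mol: Molecule,
    property_values: np.ndarray,
    grid: Optional[np.ndarray] = None,
    b: float = DEFAULT_RDF_B,
    coords: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Gaussian-smoothed radial distribution of pair products over the grid."""
    p, squeeze = _as_matrix(property_values, mol.n_atoms)
    if grid is None:
        grid = rdf_grid()
    if coords is None:
        coords = mol.coords_array()
    out = np.zeros((len(grid), p.shape[1]))
    n = mol.n_atoms
    if n > 1:
        ii, jj = np.triu_indices(n, k=1)
        d = np.linalg.norm(coords[ii] - coords[jj], axis=1)
        gauss = np.exp(-b * (grid[None, :] - d[:, None]) ** 2)  # pairs x grid
        prods = p[ii] * p[jj]  # pairs x props
        out = gauss.T @ prods
    return out[:, 0] if squeeze else out


def weighted_property(property_values: np.ndarray, vdw_surface_areas: np.ndarray) -> np.ndarray:
    """Elementwise VdW-surface weighting p_i * A_i."""
    p = np.asarray(property_values, dtype=float)
    a = np.asarray(vdw_surface_areas, dtype=float)
    if p.shape[0] != a.shape[0]:
        raise ValueError(f"length mismatch: {p.shape[0]} properties vs {a.shape[0]} areas")
    return p * (a if p.ndim == 1 else a[:, None])


# ---------------------------------------------------------------------------
# Feature-matrix assembly
# ---------------------------------------------------------------------------

def featurize_molecule(mol: Molecule, config: DescriptorConfig) -> np.ndarray:
    """Descriptor row for one molecule, in config order."""
    needs_table = any(g.kind != "scalar" for g in config.groups)
    table = compute_atom_property_table(mol) if needs_table else None
    distances = None
    scalars = None
    parts: list[np.ndarray] = []
    prop_matrix = table[list(PROPERTY_IDS)].to_numpy() if table is not None else None
    areas = table[VDW_SURFACE_AREA].to_numpy() if table is not None else None
    coords = mol.coords_array() if (
        table is not None and any(g.needs_coords for g in config.groups)
    ) else None
    prop_index = {p: k for k, p in enumerate(PROPERTY_IDS)}

    for group in config.groups:
        if group.kind == "scalar":
            if scalars is None:
                scalars = scalar_descriptors(mol)
            parts.append(np.array([scalars[SCALAR_NAMES.index(group.name)]]))
            continue
        p = prop_matrix[:, prop_index[group.property_id]]
        if group.weighted:
            p = weighted_property(p, areas)
        if group.kind == "ac2d":
            if distances is None:
                distances = topological_distances(mol)
            parts.append(autocorrelation_2d(mol, p, group.n_bins, distances=distances))
        elif group.kind == "ac3d":
            parts.append(
                autocorrelation_3d(mol, p, group.n_bins, group.bin_width, coords=coords)
            )
        else:
            grid = rdf_grid(group.n_bins)
            parts.append(radial_distribution(mol, p, grid, group.rdf_b, coords=coords))
    return np.concatenate(parts)


def assemble_feature_matrix(
    library: Sequence[Molecule],
    config: Optional[DescriptorConfig] = None,
) -> FeatureMatrix:
    """Featurize a molecule library; failing molecules are excluded and logged."""
    if config is None:
        config = DescriptorConfig.default()
    if any(g.needs_coords for g in config.groups):
        missing = [m.id for m in library if not m.has_coords]
        if missing:
            raise NoGeometryError(
                f"3D descriptor groups requested but {len(missing)} molecule(s) "
                f"lack coordinates (first: {missing[0]!r})"
            )
    columns: list[str] = []
    for g in config.groups:
        columns.extend(g.column_names())
    rows = []
    ids = []
    n_failed = 0
    for mol in library:
        try:
            rows.append(featurize_molecule(mol, config))
            ids.append(mol.id)
        except Exception as exc:  # noqa: BLE001 - per-molecule error report
            n_failed += 1
            logger.warning("featurization failed for %r: %s", mol.id, exc)
    if n_failed:
        logger.warning("assemble_feature_matrix: %d molecule(s) excluded", n_failed)
    frame = pd.DataFrame(
        np.vstack(rows) if rows else np.zeros((0, len(columns))),
        index=pd.Index(ids, name="compound_id"),
        columns=columns,
    )
    group_columns = {g.name: g.column_names() for g in config.groups}
    return FeatureMatrix(frame=frame, group_columns=group_columns)


class MinMaxScaler:
    """Per-column min-max scaling to [0, 1], fitted on the training partition."""

    def __init__(self) -> None:
        self.lo: Optional[np.ndarray] = None
        self.span: Optional[np.ndarray] = None

    def fit(self, x: np.ndarray) -> "MinMaxScaler":
        x = np.asarray(x, dtype=float)
        self.lo = x.min(axis=0)
        span = x.max(axis=0) - self.lo
        self.span = np.where(span > 0, span, 1.0)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.lo is None:
            raise RuntimeError("scaler not fitted")
        return (np.asarray(x, dtype=float) - self.lo) / self.span

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)
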