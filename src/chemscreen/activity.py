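"""Activity labeling, assay set-algebra curation and dataset assembly.

HTS outcomes are mapped onto a single regression scale: active compounds
with a measured IC50/EC50 get pIC50 = -log10(potency / 1 M); actives without
a measurement get a representative 1 µM (pIC50 = 6); inactives get 1 mM
(pIC50 = 3).  Thresholding at 3 recovers the binary labels.

Curation combines confirmatory and counter screens with set algebra
(union / intersect / subtract) over per-assay active/inactive compound sets;
the nine benchmark recipes ship as JSON data files.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .descriptors import FeatureMatrix

logger = logging.getLogger(__name__)

INACTIVE_POTENCY_M = 1e-3  # 1 mM
DEFAULT_ACTIVE_POTENCY_M = 1e-6  # representative 1 µM
INACTIVE_P_ACTIVITY = 3.0


class CurationError(ValueError):
    """Ill-formed recipe or missing assay table."""


@dataclass
class ActivityRecord:
    """Outcome for one compound: binary label plus the p-activity value."""

    compound_id: str
    is_active: bool
    raw_potency: Optional[float] = None  # molar
    potency_kind: str = "none"  # IC50 | EC50 | none
    p_activity: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if math.isnan(self.p_activity):
            self.p_activity = _p_activity(self.is_active, self.raw_potency)


def _p_activity(is_active: bool, raw_potency: Optional[float]) -> float:
    if not is_active:
        return INACTIVE_P_ACTIVITY
    potency = DEFAULT_ACTIVE_POTENCY_M if raw_potency is None else raw_potency
    if potency <= 0:
        raise ValueError(f"potency must be positive, got {potency}")
    return -math.log10(potency / 1.0)


def p_activity_transform(record: ActivityRecord) -> ActivityRecord:
    """Return the record with p_activity (and default potency) filled in."""
    potency = record.raw_potency
    if record.is_active and potency is None:
        potency = DEFAULT_ACTIVE_POTENCY_M
    if not record.is_active:
        potency = INACTIVE_POTENCY_M
    return ActivityRecord(
        compound_id=record.compound_id,
        is_active=record.is_active,
        raw_potency=potency,
        potency_kind=record.potency_kind,
        p_activity=_p_activity(record.is_active, potency),
    )


@dataclass
class AssayOutcomeTable:
    """Outcomes of one assay (AID): compound id → active / inactive."""

    assay_id: str
    outcomes: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.outcomes.values()} - {"active", "inactive"}
        if bad:
            raise ValueError(f"unknown outcome value(s) {bad} in assay {self.assay_id}")

    def ids(self, which: str) -> set[str]:
        return {cid for cid, out in self.outcomes.items() if out == which}

    @property
    def active_ids(self) -> set[str]:
        return self.ids("active")

    @property
    def inactive_ids(self) -> set[str]:
        return self.ids("inactive")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "list[AssayOutcomeTable]":
        tables = []
        for aid, sub in frame.groupby("assay_id"):
            outcomes = dict(zip(sub["compound_id"].astype(str), sub["outcome"]))
            tables.append(cls(assay_id=str(aid), outcomes=outcomes))
        return tables

    @classmethod
    def read_csv(cls, path: Union[str, Path]) -> "list[AssayOutcomeTable]":
        return cls.from_frame(pd.read_csv(path, dtype={"compound_id": str, "assay_id": str}))


@dataclass
class CurationRecipe:
    """Set expression over assay outcome sets plus the inactive source assays.

    ``expression`` is a nested dict: leaves ``{"assay": aid, "set": "active"}``,
    internal nodes ``{"op": "union"|"intersect"|"subtract", "args": [...]}``.
    ``subtract`` is left-associative over its arguments.
    """

    said: str
    expression: dict
    inactive_source: list[str]

    @classmethod
    def from_json(cls, source: Union[str, Path, dict]) -> "CurationRecipe":
        payload = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        inactive = payload["inactive_source"]
        if isinstance(inactive, str):
            inactive = [inactive]
        return cls(said=str(payload["said"]), expression=payload["expression"],
                   inactive_source=[str(a) for a in inactive])

    def referenced_assays(self) -> set[str]:
        out: set[str] = set(self.inactive_source)

        def walk(node: dict) -> None:
            if "assay" in node:
                out.add(str(node["assay"]))
                return
            for arg in node["args"]:
                walk(arg)

        walk(self.expression)
        return out


def load_recipe(said: Union[str, int]) -> CurationRecipe:
    """Load one of the packaged benchmark curation recipes by summary-assay id."""
    name = f"said_{said}.json"
    path = resources.files("chemscreen").joinpath(f"data/recipes/{name}")
    if not path.is_file():
        raise CurationError(f"no packaged recipe for SAID {said}")
    with path.open() as fh:
        return CurationRecipe.from_json(json.load(fh))


def packaged_recipe_ids() -> list[str]:
    root = resources.files("chemscreen").joinpath("data/recipes")
    return sorted(
        p.name[len("said_"):-len(".json")]
        for p in root.iterdir()
        if p.name.startswith("said_")
    )


def _eval_expression(node: dict, tables: dict[str, AssayOutcomeTable]) -> set[str]:
    if "assay" in node:
        aid = str(node["assay"])
        if aid not in tables:
            raise CurationError(f"expression references unknown assay {aid!r}")
        return tables[aid].ids(node.get("set", "active"))
    op = node["op"]
    args = [_eval_expression(a, tables) for a in node["args"]]
    if not args:
        raise CurationError(f"operator {op!r} with no arguments")
    acc = args[0]
    for nxt in args[1:]:
        if op == "union":
            acc = acc | nxt
        elif op == "intersect":
            acc = acc & nxt
        elif op == "subtract":
            acc = acc - nxt
        else:
            raise CurationError(f"unknown operator {op!r}")
    return acc


def curate(
    recipe: CurationRecipe, tables: Sequence[AssayOutcomeTable]
) -> tuple[set[str], set[str]]:
    """Evaluate a curation recipe → (active_ids, inactive_ids), disjoint."""
    by_id = {t.assay_id: t for t in tables}
    missing = recipe.referenced_assays() - set(by_id)
    if missing:
        raise CurationError(f"recipe {recipe.said}: missing assay table(s) {sorted(missing)}")
    active = _eval_expression(recipe.expression, by_id)
    if not active:
        logger.warning("recipe %s produced an empty active set", recipe.said)
    inactive: set[str] = set()
    for aid in recipe.inactive_source:
        inactive |= by_id[aid].inactive_ids
    inactive -= active
    return active, inactive


def dataset_stats(active_ids: Sequence, inactive_ids: Sequence) -> dict:
    """Hit rate (%) and inactives-to-actives ratio, Table-style rounding."""
    n_active = len(active_ids)
    n_inactive = len(inactive_ids)
    if n_active == 0:
        raise ValueError("ratio undefined: no active compounds")
    hit_rate = round(100.0 * n_active / (n_active + n_inactive), 2)
    ratio = round(n_inactive / n_active)
    return {
        "n_active": n_active,
        "n_inactive": n_inactive,
        "hit_rate": hit_rate,
        "inactive_to_active_ratio": int(ratio),
    }


@dataclass
class QsarDataset:
    """Aligned features + activity records, the unit of training/evaluation."""

    features: FeatureMatrix
    records: list[ActivityRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.features.compound_ids
        rec_ids = [r.compound_id for r in self.records]
        if ids != rec_ids:
            raise ValueError("feature rows and activity records are not aligned")

    @property
    def y(self) -> np.ndarray:
        return np.array([r.p_activity for r in self.records])

    @property
    def is_active(self) -> np.ndarray:
        return np.array([r.is_active for r in self.records], dtype=bool)

    @property
    def compound_ids(self) -> list[str]:
        return self.features.compound_ids

    def x(self, groups: Optional[Sequence[str]] = None) -> np.ndarray:
        if groups is None:
            groups = self.features.group_names
        return self.features.values_for_groups(list(groups))


def reduce_inactives(
    split_indices: dict[str, np.ndarray],
    is_active: np.ndarray,
    n_train: int = 30_000,
    n_monitor: int = 10_000,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Randomly thin inactives in the training/monitoring partitions.

    All actives are kept; the independent partition is never altered.  Fewer
    inactives than requested → keep all (logged).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    budgets = {"train": n_train, "monitor": n_monitor}
    for role, idx in split_indices.items():
        idx = np.asarray(idx)
        if role not in budgets:
            out[role] = idx
            continue
        budget = budgets[role]
        inactive_idx = idx[~is_active[idx]]
        active_idx = idx[is_active[idx]]
        if len(inactive_idx) > budget:
            keep = rng.choice(len(inactive_idx), size=budget, replace=False)
            inactive_idx = inactive_idx[np.sort(keep)]
        else:
            logger.info(
                "reduce_inactives: %s partition has %d <= %d inactives, keeping all",
                role, len(inactive_idx), budget,
            )
        out[role] = np.sort(np.concatenate([active_idx, inactive_idx]))
    return out


def oversample_actives(indices: np.ndarray, is_active: np.ndarray) -> np.ndarray:
    """Replicate active rows cyclically until actives >= inactives.

    Applied to ANN/SVM training partitions only; monitoring and independent
    partitions are never oversampled.
    """
    indices = np.asarray(indices)
    active_idx = indices[is_active[indices]]
    inactive_idx = indices[~is_active[indices]]
    n_active, n_inactive = len(active_idx), len(inactive_idx)
    if n_active == 0 or n_inactive == 0 or n_active >= n_inactive:
        return indices
    reps = int(np.ceil(n_inactive / n_active))
    replicated = np.tile(active_idx, reps)[:n_inactive]
    return np.concatenate([replicated, inactive_idx])
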