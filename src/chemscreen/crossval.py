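"""Cross-validation plans for QSAR model training.

Compounds are split into k equal partitions, stratified by class.  In every
split one partition is the independent evaluation set, one the monitoring
set (early termination / tuning), and the remaining k-2 form the training
set (80% of the data for k=10).

* ``full`` mode enumerates every ordered (independent, monitoring) pair:
  k*(k-1) splits — 90 for k=10 — so every compound serves in an independent
  partition at least once.
* ``reduced`` mode (descriptor selection) fixes partition 0 as independent
  and cycles the monitoring partition over the rest: k-1 splits.  The
  default reduced plan uses k=6 partitions, giving 5 splits.

Partition assignment is keyed by a stable hash of the compound id plus the
seed, so the same compounds always land in the same partitions regardless of
row order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

DEFAULT_K = 10
DEFAULT_K_REDUCED = 6  # yields the 5-split reduced plan


@dataclass(frozen=True)
class DataSplit:
    independent: int
    monitoring: int
    training: frozenset[int]

    def __post_init__(self) -> None:
        roles = {self.independent, self.monitoring} | self.training
        if self.independent == self.monitoring or len(roles) != 2 + len(self.training):
            raise ValueError("independent, monitoring and training partitions must be distinct")


@dataclass
class CvPlan:
    k: int
    mode: str
    splits: list[DataSplit]
    seed: int = 0

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "k": self.k,
            "mode": self.mode,
            "seed": self.seed,
            "splits": [
                {
                    "independent": s.independent,
                    "monitoring": s.monitoring,
                    "training": sorted(s.training),
                }
                for s in self.splits
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CvPlan":
        payload = json.loads(Path(path).read_text())
        splits = [
            DataSplit(s["independent"], s["monitoring"], frozenset(s["training"]))
            for s in payload["splits"]
        ]
        return cls(k=payload["k"], mode=payload["mode"], splits=splits, seed=payload["seed"])


def make_cv_plan(k: int = DEFAULT_K, mode: str = "full", seed: int = 0) -> CvPlan:
    """Enumerate the deterministic train/monitor/independent assignments."""
    if k < 3:
        raise ValueError("need at least 3 partitions")
    partitions = set(range(k))
    splits: list[DataSplit] = []
    if mode == "full":
        for independent in range(k):
            for monitoring in range(k):
                if monitoring == independent:
                    continue
                training = frozenset(partitions - {independent, monitoring})
                splits.append(DataSplit(independent, monitoring, training))
    elif mode == "reduced":
        independent = 0
        for monitoring in range(1, k):
            training = frozenset(partitions - {independent, monitoring})
            splits.append(DataSplit(independent, monitoring, training))
    else:
        raise ValueError(f"unknown CV mode {mode!r}")
    return CvPlan(k=k, mode=mode, splits=splits, seed=seed)


def _stable_key(seed: int, compound_id: str) -> int:
    digest = hashlib.md5(f"{seed}:{compound_id}".encode()).hexdigest()
    return int(digest, 16)


def partition_dataset(
    compound_ids: Sequence[str], is_active: np.ndarray, k: int, seed: int = 0
) -> np.ndarray:
    """Stratified partition labels in [0, k), deterministic and id-keyed.

    Actives and inactives are partitioned separately so every partition holds
    a near-equal share of each class (sizes within each class differ by <=1).
    """
    is_active = np.asarray(is_active, dtype=bool)
    if len(compound_ids) != len(is_active):
        raise ValueError("compound_ids and is_active lengths differ")
    labels = np.full(len(compound_ids), -1, dtype=int)
    for cls_mask in (is_active, ~is_active):
        idx = np.nonzero(cls_mask)[0]
        if len(idx) < k:
            raise ValueError(
                f"class with {len(idx)} members cannot fill {k} partitions"
            )
        keys = np.array([_stable_key(seed, str(compound_ids[i])) for i in idx])
        order = idx[np.argsort(keys, kind="stable")]
        for part, chunk in enumerate(np.array_split(order, k)):
            labels[chunk] = part
    return labels


def split_indices(partition_labels: np.ndarray, split: DataSplit) -> dict[str, np.ndarray]:
    """Row indices for the three roles of one split."""
    labels = np.asarray(partition_labels)
    return {
        "train": np.nonzero(np.isin(labels, list(split.training)))[0],
        "monitor": np.nonzero(labels == split.monitoring)[0],
        "independent": np.nonzero(labels == split.independent)[0],
    }
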