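"""High-level orchestration of the screening benchmark on synthetic data.

These helpers chain the library stages — fixture generation, featurization,
reduced-CV descriptor selection, training of the four learners, and
consensus evaluation — into the standard self-contained benchmark run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .activity import QsarDataset, oversample_actives
from .crossval import (
    DEFAULT_K_REDUCED,
    make_cv_plan,
    partition_dataset,
    split_indices,
)
from .descriptors import DescriptorConfig, assemble_feature_matrix
from .evaluation import (
    ConsensusRanking,
    consensus_ranking,
    tnr_tpr_curve,
)
from .feature_selection import SelectionTrajectory, sffs
from .learners import (
    ModelSpec,
    TrainedModel,
    predict,
    train_ann,
    train_dt,
    train_kn,
    train_svr,
)
from .synthetic import FixtureSpec, generate_activity, generate_library

logger = logging.getLogger(__name__)

METHODS = ("ANN", "SVM", "DT", "KN")


def build_standard_dataset(
    n_compounds: int = 5000,
    seed: int = 0,
    active_fraction: float = 0.01,
    config: Optional[DescriptorConfig] = None,
) -> QsarDataset:
    """Standard benchmark fixture: 1:100 class ratio, one informative group."""
    spec = FixtureSpec(
        n_compounds=n_compounds, seed=seed, base_active_fraction=active_fraction
    )
    library = generate_library(spec)
    records = generate_activity(library, spec)
    features = assemble_feature_matrix(library, config or DescriptorConfig.default())
    return QsarDataset(
        features=features,
        records=records,
        provenance={"fixture": spec.__dict__, "seed": seed},
    )


def reduced_cv_sffs(
    dataset: QsarDataset,
    seed: int = 0,
    k: int = DEFAULT_K_REDUCED,
    max_rounds: Optional[int] = None,
    patience: int = 10,
) -> SelectionTrajectory:
    """SFFS over descriptor groups with a decision-tree wrapper model.

    Each candidate set is scored by the mean monitoring-partition TNR-TPR
    integral over the reduced cross-validation splits (the fixed independent
    partition stays untouched during selection).
    """
    labels = partition_dataset(dataset.compound_ids, dataset.is_active, k=k, seed=seed)
    plan = make_cv_plan(k=k, mode="reduced", seed=seed)
    y = dataset.y
    is_active = dataset.is_active

    def trainer(groups: tuple[str, ...]):
        x = dataset.x(groups)
        models = []
        for split in plan.splits:
            roles = split_indices(labels, split)
            model = train_dt(x[roles["train"]], y[roles["train"]],
                             ModelSpec("DT", seed=seed))
            models.append((model, x[roles["monitor"]], is_active[roles["monitor"]]))
        return models

    def objective(entry) -> float:
        model, x_mon, labels_mon = entry
        return tnr_tpr_curve(predict(model, x_mon), labels_mon).integral()

    return sffs(dataset.features.group_names, trainer, objective,
                patience=patience, max_rounds=max_rounds)


def train_selected_methods(
    dataset: QsarDataset,
    groups: Sequence[str],
    seed: int = 0,
    k: int = 10,
    split_index: int = 0,
    ann_epochs: int = 200,
) -> tuple[dict[str, list[TrainedModel]], dict[str, np.ndarray]]:
    """Train all four learners on one full-CV split of the selected groups.

    Returns the per-method models plus the independent-partition arrays used
    for evaluation.  ANN/SVM training partitions are oversampled; DT and KN
    are trained on the raw class ratio.
    """
    labels = partition_dataset(dataset.compound_ids, dataset.is_active, k=k, seed=seed)
    plan = make_cv_plan(k=k, mode="full", seed=seed)
    roles = split_indices(labels, plan.splits[split_index])
    x = dataset.x(groups)
    y = dataset.y
    is_active = dataset.is_active
    columns = tuple(
        c for g in groups for c in dataset.features.group_columns[g]
    )
    balanced = oversample_actives(roles["train"], is_active)
    models: dict[str, list[TrainedModel]] = {
        "ANN": [train_ann(x[balanced], y[balanced], x[roles["monitor"]],
                          y[roles["monitor"]],
                          ModelSpec("ANN", {"epochs": ann_epochs}, seed=seed),
                          columns=columns)],
        "SVM": [train_svr(x[balanced], y[balanced], ModelSpec("SVM", seed=seed),
                          columns=columns)],
        "DT": [train_dt(x[roles["train"]], y[roles["train"]],
                        ModelSpec("DT", seed=seed), columns=columns)],
        "KN": [train_kn(x[roles["train"]], y[roles["train"]],
                        ModelSpec("KN", seed=seed), columns=columns)],
    }
    independent = {
        "x": x[roles["independent"]],
        "labels": is_active[roles["independent"]],
        "y": y[roles["independent"]],
    }
    return models, independent


@dataclass
class BenchmarkReport:
    selected_groups: tuple[str, ...]
    first_round_group: str
    method_integrals: dict[str, float]
    ranking: ConsensusRanking

    @property
    def best_single_enr(self) -> float:
        return self.ranking.best_single.enr

    @property
    def best_consensus_enr(self) -> float:
        return self.ranking.best_consensus.enr


def run_standard_benchmark(
    seed: int = 0,
    n_compounds: int = 5000,
    sffs_rounds: Optional[int] = 1,
    tpr_target: float = 0.25,
) -> BenchmarkReport:
    """Fixture → featurize → select → train four learners → consensus."""
    dataset = build_standard_dataset(n_compounds=n_compounds, seed=seed)
    trajectory = reduced_cv_sffs(dataset, seed=seed, max_rounds=sffs_rounds)
    groups = trajectory.selected_groups
    models, independent = train_selected_methods(dataset, groups, seed=seed)
    integrals = {
        m: tnr_tpr_curve(
            predict(models[m][0], independent["x"]), independent["labels"]
        ).integral()
        for m in METHODS
    }
    ranking = consensus_ranking(
        models, independent["x"], independent["labels"], tpr_target=tpr_target
    )
    return BenchmarkReport(
        selected_groups=groups,
        first_round_group=trajectory.rounds[0].chosen_group,
        method_integrals=integrals,
        ranking=ranking,
    )
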