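"""Model quality analysis for virtual screening.

The central object is the TNR-TPR curve: the ROC curve rotated 90°
clockwise, plotting specificity (true-negative rate) against sensitivity
(true-positive rate) over a descending sweep of score thresholds.  Its full
integral equals the ROC AUC (0.5 for a random predictor); the partial
integral from TPR 0 to a cutoff (0.25 by default) emphasises early
recognition, which is what matters when only the top-ranked fraction of a
screened library is tested.

Enrichment (ENR) is the complementary single number: precision at the
threshold reaching the TPR target, divided by the library's baseline active
fraction — the factor by which screening concentrates actives.

Consensus prediction averages the predicted p-activities over the
cross-validated models of one or more learner types; ``consensus_ranking``
scores every non-empty method subset and ranks them by ENR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .learners import TrainedModel, predict

DEFAULT_TPR_TARGET = 0.25


class SingleClassError(ValueError):
    """Curve/enrichment analysis needs both classes present."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.fp + self.tn

    @property
    def tpr(self) -> float:
        return self.tp / self.p if self.p else 0.0

    @property
    def tnr(self) -> float:
        return self.tn / self.n if self.n else 0.0


@dataclass
class TnrTprCurve:
    """Threshold sweep points ordered by non-decreasing TPR.

    Tied scores are treated as one atomic threshold step (no intra-tie
    interpolation).
    """

    tpr: np.ndarray
    tnr: np.ndarray
    thresholds: np.ndarray  # aligned with points after the (0, 1) start point

    def integral(self, tpr_max: float = 1.0) -> float:
        return integral_to_cutoff(self, tpr_max)


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise SingleClassError("need both active and inactive compounds")
    return labels


def tnr_tpr_curve(scores: np.ndarray, labels: np.ndarray) -> TnrTprCurve:
    """Sweep unique score thresholds in descending order."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    p = labels.sum()
    n = len(labels) - p
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    cum_tp = np.cumsum(sorted_labels)
    cum_fp = np.cumsum(~sorted_labels)
    # last index of each tied block = one atomic threshold step
    block_ends = np.nonzero(np.append(np.diff(sorted_scores) != 0, True))[0]
    tpr = np.concatenate([[0.0], cum_tp[block_ends] / p])
    tnr = np.concatenate([[1.0], (n - cum_fp[block_ends]) / n])
    thresholds = sorted_scores[block_ends]
    return TnrTprCurve(tpr=tpr, tnr=tnr, thresholds=thresholds)


def integral_to_cutoff(curve: TnrTprCurve, tpr_max: float = DEFAULT_TPR_TARGET) -> float:
    """Trapezoidal integral of TNR over TPR in [0, tpr_max] (max value tpr_max)."""
    if not 0 < tpr_max <= 1:
        raise ValueError("tpr_max must lie in (0, 1]")
    tpr, tnr = curve.tpr, curve.tnr
    if tpr_max < tpr[-1]:
        # interpolate the curve at tpr_max within its containing segment
        j = int(np.searchsorted(tpr, tpr_max, side="right"))
        t0, t1 = tpr[j - 1], tpr[j]
        frac = 0.0 if t1 == t0 else (tpr_max - t0) / (t1 - t0)
        y = curve.tnr[j - 1] + frac * (curve.tnr[j] - curve.tnr[j - 1])
        tpr = np.concatenate([tpr[:j], [tpr_max]])
        tnr = np.concatenate([tnr[:j], [y]])
    return float(np.trapezoid(tnr, tpr))


@dataclass
class EnrichmentReport:
    tpr_target: float
    achieved_tpr: float
    enr: float
    confusion: ConfusionCounts
    baseline_active_fraction: float

    @property
    def theoretical_max(self) -> float:
        return 1.0 / self.baseline_active_fraction


def enrichment(
    scores: np.ndarray, labels: np.ndarray, tpr_target: float = DEFAULT_TPR_TARGET
) -> EnrichmentReport:
    """Precision over baseline at the loosest cutoff reaching the TPR target."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    p = int(labels.sum())
    n = int(len(labels) - p)
    curve = tnr_tpr_curve(scores, labels)
    reachable = curve.tpr[1:] >= tpr_target
    if not reachable.any():
        raise ValueError(f"TPR target {tpr_target} not reachable by any threshold")
    j = int(np.argmax(reachable))  # first (largest) threshold reaching the target
    tp = int(round(curve.tpr[1:][j] * p))
    tn = int(round(curve.tnr[1:][j] * n))
    fp = n - tn
    fn = p - tp
    precision = tp / (tp + fp)
    base = p / (p + n)
    return EnrichmentReport(
        tpr_target=tpr_target,
        achieved_tpr=tp / p,
        enr=precision / base,
        confusion=ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn),
        baseline_active_fraction=base,
    )


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def consensus_predict(models: Sequence[TrainedModel], x: np.ndarray) -> np.ndarray:
    """Unweighted mean of predicted p-activities across models."""
    if not models:
        raise ValueError("no models given")
    fingerprints = {m.fingerprint for m in models}
    if len(fingerprints) != 1:
        raise ValueError("models use different descriptor sets; refusing to average")
    return np.mean([predict(m, x) for m in models], axis=0)


@dataclass
class ConsensusRow:
    methods: tuple[str, ...]
    integral: float  # partial TNR-TPR integral to the TPR target
    enr: float
    rank: int = 0


@dataclass
class ConsensusRanking:
    rows: list[ConsensusRow]
    best_single: ConsensusRow
    best_consensus: ConsensusRow
    diff_percent: float
    inactive_to_active_ratio: int


def consensus_ranking(
    method_models: dict[str, Sequence[TrainedModel]],
    x: np.ndarray,
    labels: np.ndarray,
    tpr_target: float = DEFAULT_TPR_TARGET,
    inactive_to_active_ratio: Optional[int] = None,
) -> ConsensusRanking:
    """Evaluate every non-empty subset of learner types on independent data.

    Rows are ranked by ENR (ties: fewer methods first).  ``diff_percent`` is
    the ENR gain of the best multi-method consensus over the best single
    predictor, normalized by the (rounded) inactives-to-actives ratio,
    in percent.
    """
    if not method_models:
        raise ValueError("need at least one method")
    labels = _check_labels(labels)
    if inactive_to_active_ratio is None:
        p = int(labels.sum())
        inactive_to_active_ratio = int(round((len(labels) - p) / p))
    methods = sorted(method_models)
    rows: list[ConsensusRow] = []
    for size in range(1, len(methods) + 1):
        for subset in combinations(methods, size):
            models: list[TrainedModel] = []
            for m in subset:
                models.extend(method_models[m])
            scores = consensus_predict(models, x)
            curve = tnr_tpr_curve(scores, labels)
            rows.append(
                ConsensusRow(
                    methods=subset,
                    integral=integral_to_cutoff(curve, tpr_target),
                    enr=enrichment(scores, labels, tpr_target).enr,
                )
            )
    rows.sort(key=lambda r: (-r.enr, len(r.methods)))
    for i, row in enumerate(rows, start=1):
        row.rank = i
    singles = [r for r in rows if len(r.methods) == 1]
    multis = [r for r in rows if len(r.methods) > 1]
    best_single = singles[0]
    best_consensus = multis[0] if multis else singles[0]
    diff = 100.0 * (best_consensus.enr - best_single.enr) / inactive_to_active_ratio
    return ConsensusRanking(
        rows=rows,
        best_single=best_single,
        best_consensus=best_consensus,
        diff_percent=diff,
        inactive_to_active_ratio=inactive_to_active_ratio,
    )
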