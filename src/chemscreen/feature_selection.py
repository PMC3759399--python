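"""Descriptor ranking (information gain, F-score) and sequential forward
feature selection over descriptor groups.

IG and F-score rate single descriptor columns by how well they separate
active from inactive compounds; a group's score is the maximum over its
member columns, so any single discriminating bin promotes the whole group.
SFFS is the wrapper alternative: a greedy round-wise search that adds the
group maximizing the cross-validated model objective, terminating after ten
rounds without improvement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .descriptors import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_PREFIX_SIZES = (1, 2, 4, 8, 16, 32, 60)


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(values: np.ndarray, labels: np.ndarray) -> float:
    """Entropy reduction of the best single binary threshold on the column.

    Candidate thresholds are midpoints between consecutive sorted distinct
    values; the score lies in [0, H(labels)] bits.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n = len(values)
    if labels.all() or not labels.any():
        raise ValueError("information gain needs both classes present")
    h_total = _entropy(np.array([labels.sum(), n - labels.sum()]))
    order = np.argsort(values, kind="stable")
    v_sorted = values[order]
    y_sorted = labels[order]
    cum_pos = np.cumsum(y_sorted)
    boundaries = np.nonzero(np.diff(v_sorted) > 0)[0]  # split after index b
    if len(boundaries) == 0:
        return 0.0
    n_left = boundaries + 1
    pos_left = cum_pos[boundaries]
    neg_left = n_left - pos_left
    pos_right = labels.sum() - pos_left
    neg_right = (n - n_left) - pos_right

    def h(pos, neg):
        tot = pos + neg
        out = np.zeros(len(tot))
        for arr in (pos, neg):
            frac = np.divide(arr, tot, out=np.zeros(len(tot)), where=tot > 0)
            nz = frac > 0
            out[nz] -= frac[nz] * np.log2(frac[nz])
        return out

    cond = (n_left / n) * h(pos_left, neg_left) + ((n - n_left) / n) * h(pos_right, neg_right)
    return float(h_total - cond.min())


def f_score(values: np.ndarray, labels: np.ndarray) -> float:
    """Fisher-style column score from class means and variances.

    F = ((m+ - m)^2 + (m- - m)^2) / (s+^2 + s-^2) with n-1 variances.
    A zero denominator gives +inf for separated means, 0 otherwise.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = values[labels]
    neg = values[~labels]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("f_score needs at least two members per class")
    m = values.mean()
    num = (pos.mean() - m) ** 2 + (neg.mean() - m) ** 2
    den = pos.var(ddof=1) + neg.var(ddof=1)
    if den == 0:
        return float("inf") if num > 0 else 0.0
    return float(num / den)


_COLUMN_SCORERS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "IG": information_gain,
    "FS": f_score,
}


def rank_groups(
    matrix: FeatureMatrix, labels: np.ndarray, method: str = "IG"
) -> list[tuple[str, float]]:
    """Descending group ranking; group score = max over member columns.

    Ties keep the original group order.  Constant columns score 0 under both
    metrics.
    """
    scorer = _COLUMN_SCORERS.get(method)
    if scorer is None:
        raise ValueError(f"unknown ranking method {method!r} (use IG or FS)")
    labels = np.asarray(labels, dtype=bool)
    scores = []
    for gi, (group, cols) in enumerate(matrix.group_columns.items()):
        best = 0.0
        for col in cols:
            col_values = matrix.frame[col].to_numpy(dtype=float)
            if np.all(col_values == col_values[0]):
                continue
            best = max(best, scorer(col_values, labels))
        scores.append((group, best, gi))
    scores.sort(key=lambda t: (-t[1], t[2]))
    return [(g, s) for g, s, _ in scores]


@dataclass
class SelectionRound:
    round_index: int
    chosen_group: str
    objective_mean: float
    objective_std: float
    cumulative_groups: tuple[str, ...]


@dataclass
class SelectionTrajectory:
    rounds: list[SelectionRound] = field(default_factory=list)
    selected_groups: tuple[str, ...] = ()
    best_objective: float = float("-inf")

    @property
    def best_so_far(self) -> list[float]:
        out, best = [], float("-inf")
        for r in self.rounds:
            best = max(best, r.objective_mean)
            out.append(best)
        return out


def sffs(
    groups: Sequence[str],
    trainer: Callable[[tuple[str, ...]], Sequence],
    objective: Callable[[object], float],
    patience: int = 10,
    max_rounds: Optional[int] = None,
) -> SelectionTrajectory:
    """Greedy forward selection over descriptor groups.

    ``trainer(candidate_groups)`` trains the reduced-CV model set for a
    candidate descriptor set; ``objective(model)`` scores one model (mean
    TNR-TPR integral across models drives the selection).  Stops when all
    groups are added, after ``patience`` rounds without improvement, or at
    ``max_rounds``.  Returns the best cumulative set ever seen.
    """
    remaining = list(groups)
    current: tuple[str, ...] = ()
    traj = SelectionTrajectory()
    rounds_without_improvement = 0
    round_index = 0
    while remaining:
        if max_rounds is not None and round_index >= max_rounds:
            break
        round_index += 1
        best_candidate = None
        best_scores: Optional[np.ndarray] = None
        for group in remaining:  # original order breaks ties by lower index
            candidate = current + (group,)
            try:
                models = trainer(candidate)
            except Exception as exc:  # noqa: BLE001 - candidate skipped, logged
                logger.warning("SFFS: trainer failed on %s: %s", candidate, exc)
                continue
            scores = np.array([objective(m) for m in models], dtype=float)
            if best_scores is None or scores.mean() > best_scores.mean():
                best_candidate, best_scores = group, scores
        if best_candidate is None:
            break
        current = current + (best_candidate,)
        remaining.remove(best_candidate)
        mean = float(best_scores.mean())
        std = float(best_scores.std())
        traj.rounds.append(
            SelectionRound(round_index, best_candidate, mean, std, current)
        )
        if mean > traj.best_objective:
            traj.best_objective = mean
            traj.selected_groups = current
            rounds_without_improvement = 0
        else:
            rounds_without_improvement += 1
            if rounds_without_improvement >= patience:
                break
    return traj


def evaluate_prefix_sizes(
    ranking: Sequence[tuple[str, float]],
    trainer: Callable[[tuple[str, ...]], Sequence],
    objective: Callable[[object], float],
    sizes: Sequence[int] = DEFAULT_PREFIX_SIZES,
) -> tuple[tuple[str, ...], dict[int, float]]:
    """Pick the best top-n prefix of an IG/FS ranking by cross-validated objective."""
    ranked_groups = [g for g, _ in ranking]
    results: dict[int, float] = {}
    best_prefix: tuple[str, ...] = ()
    best_score = float("-inf")
    for size in sizes:
        if size > len(ranked_groups):
            continue
        prefix = tuple(ranked_groups[:size])
        models = trainer(prefix)
        score = float(np.mean([objective(m) for m in models]))
        results[size] = score
        if score > best_score:
            best_score, best_prefix = score, prefix
    return best_prefix, results
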