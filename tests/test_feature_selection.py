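import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chemscreen.descriptors import FeatureMatrix
from chemscreen.feature_selection import (
    evaluate_prefix_sizes,
    f_score,
    information_gain,
    rank_groups,
    sffs,
)


def brute_force_ig(values, labels):
    """Enumerate every threshold (including between ties) directly."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)

    def entropy(mask):
        n = mask.sum()
        if n == 0:
            return 0.0
        p = labels[mask].sum() / n
        out = 0.0
        for frac in (p, 1 - p):
            if frac > 0:
                out -= frac * math.log2(frac)
        return out

    h = entropy(np.ones(len(values), dtype=bool))
    best = h  # threshold outside the range -> no gain
    uniq = np.unique(values)
    for lo, hi in zip(uniq, uniq[1:]):
        t = (lo + hi) / 2
        left = values <= t
        cond = left.mean() * entropy(left) + (~left).mean() * entropy(~left)
        best = min(best, cond)
    return h - best


def brute_force_f_score(values, labels):
    pos = values[labels]
    neg = values[~labels]
    m = values.mean()
    num = (pos.mean() - m) ** 2 + (neg.mean() - m) ** 2
    den = (
        sum((v - pos.mean()) ** 2 for v in pos) / (len(pos) - 1)
        + sum((v - neg.mean()) ** 2 for v in neg) / (len(neg) - 1)
    )
    if den == 0:
        return float("inf") if num > 0 else 0.0
    return num / den


class TestInformationGain:
    def test_perfect_separator_on_balanced_labels(self):
        values = np.array([0.0, 0.1, 0.9, 1.0])
        labels = np.array([True, True, False, False])
        assert information_gain(values, labels) == pytest.approx(1.0)

    def test_constant_column_zero(self):
        assert information_gain(np.ones(6), np.arange(6) < 3) == 0.0

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            information_gain(np.arange(4.0), np.ones(4, dtype=bool))

    def test_matches_exhaustive_oracle_on_example(self):
        values = np.array([1.0, 3.0, 2.0, 4.0])
        labels = np.array([True, True, False, False])
        assert information_gain(values, labels) == pytest.approx(
            brute_force_ig(values, labels)
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 25))
        values = rng.choice([0.0, 0.5, 1.0, 2.0, 3.5], size=n)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        assert information_gain(values, labels) == pytest.approx(
            brute_force_ig(values, labels), abs=1e-12
        )


class TestFScore:
    def test_hand_value(self):
        values = np.array([0.0, 1.0, 2.0, 3.0])
        labels = np.array([True, True, False, False])
        assert f_score(values, labels) == pytest.approx(2.0)

    def test_identical_distributions_zero(self):
        values = np.array([1.0, 2.0, 1.0, 2.0])
        labels = np.array([True, True, False, False])
        assert f_score(values, labels) == 0.0

    def test_zero_variance_separated_means_is_inf(self):
        values = np.array([1.0, 1.0, 2.0, 2.0])
        labels = np.array([True, True, False, False])
        assert f_score(values, labels) == float("inf")

    def test_too_few_members(self):
        with pytest.raises(ValueError):
            f_score(np.arange(3.0), np.array([True, False, False]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_spreadsheet_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        values = rng.normal(size=n)
        labels = np.zeros(n, dtype=bool)
        labels[: max(2, n // 3)] = True
        assert f_score(values, labels) == pytest.approx(
            brute_force_f_score(values, labels), rel=1e-9
        )


def matrix_from_arrays(groups: dict[str, np.ndarray]) -> FeatureMatrix:
    frame = {}
    group_columns = {}
    for name, arr in groups.items():
        arr = np.atleast_2d(arr.T).T
        cols = [f"{name}.{i}" for i in range(arr.shape[1])]
        group_columns[name] = cols
        for c, col in enumerate(cols):
            frame[col] = arr[:, c]
    df = pd.DataFrame(frame, index=[f"c{i}" for i in range(len(arr))])
    return FeatureMatrix(frame=df, group_columns=group_columns)


class TestRankGroups:
    def _planted(self, rng, n=60):
        labels = rng.random(n) < 0.4
        signal = labels.astype(float) + rng.normal(0, 0.05, n)
        noise = {f"noise{k}": rng.normal(size=(n, 3)) for k in range(4)}
        return matrix_from_arrays({"signal": signal, **noise}), labels

    @pytest.mark.parametrize("method", ["IG", "FS"])
    def test_planted_informative_group_ranks_first(self, method, rng):
        matrix, labels = self._planted(rng)
        ranking = rank_groups(matrix, labels, method=method)
        assert ranking[0][0] == "signal"

    def test_constant_matrix_all_zero_scores_original_order(self):
        matrix = matrix_from_arrays(
            {"a": np.ones((10, 2)), "b": np.ones((10, 2)), "c": np.ones(10)}
        )
        labels = np.arange(10) < 5
        ranking = rank_groups(matrix, labels, "IG")
        assert [g for g, _ in ranking] == ["a", "b", "c"]
        assert all(s == 0 for _, s in ranking)

    def test_duplicated_column_never_changes_group_score(self, rng):
        matrix, labels = self._planted(rng)
        for method in ("IG", "FS"):
            base = dict(rank_groups(matrix, labels, method))
            dup = {
                "signal": np.column_stack(
                    [matrix.frame["signal.0"], matrix.frame["signal.0"]]
                ),
                **{
                    f"noise{k}": matrix.values_for_groups([f"noise{k}"])
                    for k in range(4)
                },
            }
            scores = dict(rank_groups(matrix_from_arrays(dup), labels, method))
            assert scores["signal"] == pytest.approx(base["signal"])


class ObjectiveFixture:
    """Deterministic trainer/objective pair: each group has a fixed value and
    the objective of a set is the max of its members' values."""

    def __init__(self, values):
        self.values = values
        self.calls = []

    def trainer(self, groups):
        self.calls.append(tuple(groups))
        return [tuple(groups)]

    def objective(self, model):
        return max(self.values[g] for g in model)


class TestSffs:
    def test_informative_group_chosen_in_round_one(self):
        fx = ObjectiveFixture({"signal": 0.95, "n1": 0.5, "n2": 0.55, "n3": 0.52})
        traj = sffs(["n1", "signal", "n2", "n3"], fx.trainer, fx.objective)
        assert traj.rounds[0].chosen_group == "signal"
        assert traj.selected_groups == ("signal",)

    def test_termination_after_ten_flat_rounds(self):
        values = {"g0": 0.9, **{f"g{k}": 0.1 for k in range(1, 15)}}
        fx = ObjectiveFixture(values)
        traj = sffs(list(values), fx.trainer, fx.objective, patience=10)
        # round 1 improves; the next ten (constant objective) end the search
        assert len(traj.rounds) == 11
        assert traj.selected_groups == ("g0",)

    def test_single_group_single_round(self):
        fx = ObjectiveFixture({"only": 0.7})
        traj = sffs(["only"], fx.trainer, fx.objective)
        assert len(traj.rounds) == 1
        assert traj.selected_groups == ("only",)

    def test_best_so_far_monotone(self):
        rng = np.random.default_rng(5)
        values = {f"g{k}": float(rng.random()) for k in range(8)}
        fx = ObjectiveFixture(values)
        traj = sffs(list(values), fx.trainer, fx.objective, patience=3)
        best = traj.best_so_far
        assert all(a <= b for a, b in zip(best, best[1:]))

    def test_failing_candidate_skipped(self):
        def trainer(groups):
            if "bad" in groups:
                raise RuntimeError("boom")
            return [tuple(groups)]

        traj = sffs(["bad", "ok"], trainer, lambda m: 0.5, max_rounds=1)
        assert traj.rounds[0].chosen_group == "ok"

    def test_max_rounds_cap(self):
        fx = ObjectiveFixture({f"g{k}": 0.1 * k for k in range(6)})
        traj = sffs(list(fx.values), fx.trainer, fx.objective, max_rounds=2)
        assert len(traj.rounds) == 2


class TestPrefixEvaluation:
    def test_best_prefix_selected(self):
        scores = {1: 0.6, 2: 0.8, 4: 0.75}

        def trainer(groups):
            return [len(groups)]

        def objective(model):
            return scores[model]

        ranking = [(f"g{k}", 1.0 / (k + 1)) for k in range(4)]
        best, results = evaluate_prefix_sizes(ranking, trainer, objective, sizes=(1, 2, 4))
        assert best == ("g0", "g1")
        assert results == scores
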