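"""The four QSAR learners and their training protocols.

All learners regress the p-activity value (pIC50/pEC50 scale: 3 =
inactive, 4.6-7 = active) from min-max-normalized descriptors, so their
outputs can be thresholded, ranked and averaged on one common scale.

* ANN — one hidden layer of sigmoid units trained by "simple propagation"
  (full-batch gradient descent with learning rate η and momentum α); the
  monitoring partition drives early termination on the TNR-TPR integral and
  the best-on-monitor weights are returned.
* SVR — ε-insensitive support-vector regression with an RBF kernel
  (scikit-learn); C=1, γ=0.1 during descriptor selection, then grid-searched.
* DT — CART tree split on the Gini criterion over binary active/inactive
  labels; a leaf scores compounds by its training active fraction, mapped
  onto the p-activity scale.
* KN — Kohonen self-organizing 2D grid with a Gaussian neighbourhood of
  decaying width; a node predicts the mean training p-activity of the
  compounds it captured, empty nodes inherit from the nearest occupied node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeClassifier

from .descriptors import MinMaxScaler

logger = logging.getLogger(__name__)

#: predicted p-activity at or above this counts as "active" when a hard
#: label is needed; ranking-based measures use the raw scores
ACTIVE_CUTOFF = 3.5
#: labels are derived from training p-activities with the same cutoff
_DT_SPAN = 3.0  # leaf score s -> 3 + s * span


@dataclass
class ModelSpec:
    """Hyperparameters for one learner; unset entries fall back to defaults."""

    method: str  # ANN | SVM | DT | KN
    params: dict = field(default_factory=dict)
    seed: int = 0

    def get(self, key: str, default):
        return self.params.get(key, default)


@dataclass
class TrainedModel:
    """A fitted learner bound to its descriptor set and normalization."""

    method: str
    columns: tuple[str, ...]
    predict_fn: Callable[[np.ndarray], np.ndarray]
    scaler: Optional[MinMaxScaler] = None
    training_log: list = field(default_factory=list)
    state: dict = field(default_factory=dict)

    @property
    def fingerprint(self) -> tuple[str, ...]:
        return self.columns

    @property
    def n_features(self) -> int:
        return len(self.columns)


def predict(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Predict p-activity values for feature rows (width-checked)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {x.shape[1]} does not match model descriptor set "
            f"({model.n_features})"
        )
    out = np.asarray(model.predict_fn(x), dtype=float)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite prediction")
    return out


def _monitor_objective(
    scores: np.ndarray, labels: np.ndarray, y: Optional[np.ndarray] = None
) -> float:
    """Full-range TNR-TPR integral; a single-class monitoring partition
    falls back to negative mean squared error against the target values."""
    from .evaluation import SingleClassError, tnr_tpr_curve  # local: avoid cycle

    try:
        return tnr_tpr_curve(scores, labels).integral()
    except SingleClassError:
        if y is None:
            return float("-inf")
        return -float(np.mean((scores - np.asarray(y, dtype=float)) ** 2))


def _active_labels(y: np.ndarray) -> np.ndarray:
    return np.asarray(y) >= ACTIVE_CUTOFF


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class AnnPredictor:
    """Picklable forward pass of the trained network."""

    def __init__(self, scaler, weights, y_lo, y_span):
        self.scaler = scaler
        self.weights = [w.copy() for w in weights]
        self.y_lo = y_lo
        self.y_span = y_span

    def __call__(self, x):
        w1, b1, w2, b2 = self.weights
        h = _sigmoid(self.scaler.transform(x) @ w1 + b1)
        return ((h @ w2 + b2)[:, 0]) * self.y_span + self.y_lo


class SvrPredictor:
    def __init__(self, scaler, svr):
        self.scaler = scaler
        self.svr = svr

    def __call__(self, x):
        return self.svr.predict(self.scaler.transform(x))


class DtPredictor:
    """Leaf active-fraction score mapped onto the p-activity scale."""

    def __init__(self, tree, span):
        self.tree = tree
        self.span = span

    def leaf_scores(self, x):
        proba = self.tree.predict_proba(np.asarray(x, dtype=float))
        if proba.shape[1] == 1:  # single training class
            return np.full(len(proba), float(self.tree.classes_[0]))
        return proba[:, list(self.tree.classes_).index(1)]

    def __call__(self, x):
        return 3.0 + self.leaf_scores(x) * self.span


class KnPredictor:
    def __init__(self, scaler, weights, node_value):
        self.scaler = scaler
        self.weights = weights
        self.node_value = node_value

    def winners(self, z):
        d2 = ((z[:, None, :] - self.weights[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    def __call__(self, x):
        return self.node_value[self.winners(self.scaler.transform(np.asarray(x, dtype=float)))]


# ---------------------------------------------------------------------------
# ANN
# ---------------------------------------------------------------------------

def train_ann(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_monitor: np.ndarray,
    y_monitor: np.ndarray,
    spec: Optional[ModelSpec] = None,
    columns: Optional[Sequence[str]] = None,
) -> TrainedModel:
    """Feed-forward net with one sigmoid hidden layer, simple-propagation
    updates (η, α) and monitoring-based early termination."""
    spec = spec or ModelSpec("ANN")
    eta = spec.get("eta", 0.05)
    alpha = spec.get("alpha", 0.5)
    n_hidden = spec.get("hidden_units", 32)
    epochs = spec.get("epochs", 500)
    check_interval = spec.get("check_interval", 10)
    patience = spec.get("patience", 10)

    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    scaler = MinMaxScaler().fit(x_train)
    xt = scaler.transform(x_train)
    xm = scaler.transform(np.asarray(x_monitor, dtype=float))
    y_lo, y_hi = y_train.min(), y_train.max()
    y_span = (y_hi - y_lo) or 1.0
    yt = (y_train - y_lo) / y_span
    monitor_labels = _active_labels(y_monitor)

    rng = np.random.default_rng(spec.seed)
    d = xt.shape[1]
    w1 = rng.uniform(-0.5, 0.5, size=(d, n_hidden)) / np.sqrt(max(d, 1))
    b1 = np.zeros(n_hidden)
    w2 = rng.uniform(-0.5, 0.5, size=(n_hidden, 1)) / np.sqrt(n_hidden)
    b2 = np.zeros(1)
    vel = [np.zeros_like(w) for w in (w1, b1, w2, b2)]

    def forward(x):
        h = _sigmoid(x @ w1 + b1)
        return h, (h @ w2 + b2)[:, 0]

    def raw_predict(x):
        return forward(x)[1] * y_span + y_lo

    best = {
        "objective": _monitor_objective(raw_predict(xm), monitor_labels, y_monitor),
        "weights": [w.copy() for w in (w1, b1, w2, b2)],
    }
    training_log: list[tuple[int, float, float]] = []
    checks_without_improvement = 0
    n = len(xt)
    for epoch in range(1, epochs + 1):
        h, out = forward(xt)
        err = out - yt
        loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"ANN training diverged at epoch {epoch} (loss={loss})"
            )
        g_out = 2.0 * err[:, None] / n
        grads = [
            xt.T @ ((g_out @ w2.T) * h * (1 - h)),
            ((g_out @ w2.T) * h * (1 - h)).sum(axis=0),
            h.T @ g_out,
            g_out.sum(axis=0),
        ]
        for w, v, g in zip((w1, b1, w2, b2), vel, grads):
            v *= alpha
            v -= eta * g.reshape(w.shape)
            w += v
        if epoch % check_interval == 0 or epoch == epochs:
            objective = _monitor_objective(raw_predict(xm), monitor_labels, y_monitor)
            training_log.append((epoch, loss, objective))
            if objective > best["objective"]:
                best["objective"] = objective
                best["weights"] = [w.copy() for w in (w1, b1, w2, b2)]
                checks_without_improvement = 0
            else:
                checks_without_improvement += 1
                if checks_without_improvement >= patience:
                    break
    predict_fn = AnnPredictor(scaler, best["weights"], y_lo, y_span)
    cols = tuple(columns) if columns is not None else tuple(map(str, range(d)))
    return TrainedModel(
        method="ANN",
        columns=cols,
        predict_fn=predict_fn,
        scaler=scaler,
        training_log=training_log,
        state={"monitor_objective": best["objective"], "spec": spec},
    )


# ---------------------------------------------------------------------------
# SVR
# ---------------------------------------------------------------------------

def train_svr(
    x_train: np.ndarray,
    y_train: np.ndarray,
    spec: Optional[ModelSpec] = None,
    columns: Optional[Sequence[str]] = None,
) -> TrainedModel:
    """ε-insensitive RBF support-vector regression (C=1, γ=0.1 defaults)."""
    spec = spec or ModelSpec("SVM")
    c = spec.get("C", 1.0)
    gamma = spec.get("gamma", 0.1)
    epsilon = spec.get("epsilon", 0.1)
    x_train = np.asarray(x_train, dtype=float)
    scaler = MinMaxScaler().fit(x_train)
    svr = SVR(kernel="rbf", C=c, gamma=gamma, epsilon=epsilon)
    svr.fit(scaler.transform(x_train), np.asarray(y_train, dtype=float))
    predict_fn = SvrPredictor(scaler, svr)
    d = x_train.shape[1]
    cols = tuple(columns) if columns is not None else tuple(map(str, range(d)))
    return TrainedModel(
        method="SVM", columns=cols, predict_fn=predict_fn, scaler=scaler,
        state={"C": c, "gamma": gamma, "epsilon": epsilon, "svr": svr},
    )


DEFAULT_C_GRID = tuple(float(2.0**k) for k in range(-3, 10))
DEFAULT_GAMMA_GRID = tuple(float(2.0**k) for k in range(-9, 2))


def grid_search_svm(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_monitor: np.ndarray,
    y_monitor: np.ndarray,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    epsilon: float = 0.1,
) -> tuple[ModelSpec, TrainedModel]:
    """Exhaustive (C, γ) search selected by the monitoring TNR-TPR integral.

    Ties keep the smaller C, then the smaller γ.
    """
    if not c_grid or not gamma_grid:
        raise ValueError("grids must be non-empty")
    monitor_labels = _active_labels(y_monitor)
    best: Optional[tuple[float, ModelSpec, TrainedModel]] = None
    for c in sorted(c_grid):
        for gamma in sorted(gamma_grid):
            spec = ModelSpec("SVM", {"C": c, "gamma": gamma, "epsilon": epsilon})
            model = train_svr(x_train, y_train, spec)
            objective = _monitor_objective(
                predict(model, np.asarray(x_monitor, dtype=float)),
                monitor_labels, y_monitor,
            )
            if best is None or objective > best[0]:
                best = (objective, spec, model)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# Decision tree
# ---------------------------------------------------------------------------

def train_dt(
    x_train: np.ndarray,
    y_train: np.ndarray,
    spec: Optional[ModelSpec] = None,
    columns: Optional[Sequence[str]] = None,
) -> TrainedModel:
    """Gini CART on binary labels; leaves score by their training active
    fraction, mapped onto the p-activity scale as 3 + s * span."""
    spec = spec or ModelSpec("DT")
    labels = _active_labels(y_train)
    tree = DecisionTreeClassifier(
        criterion="gini",
        min_samples_leaf=spec.get("min_leaf", 1),
        max_depth=spec.get("max_depth", None),
        random_state=spec.seed,
    )
    x_train = np.asarray(x_train, dtype=float)
    tree.fit(x_train, labels.astype(int))
    span = spec.get("span", _DT_SPAN)
    predict_fn = DtPredictor(tree, span)
    d = x_train.shape[1]
    cols = tuple(columns) if columns is not None else tuple(map(str, range(d)))
    return TrainedModel(
        method="DT", columns=cols, predict_fn=predict_fn,
        state={"tree": tree, "span": span},
    )


# ---------------------------------------------------------------------------
# Kohonen network
# ---------------------------------------------------------------------------

def train_kn(
    x_train: np.ndarray,
    y_train: np.ndarray,
    spec: Optional[ModelSpec] = None,
    columns: Optional[Sequence[str]] = None,
) -> TrainedModel:
    """Self-organizing 2D grid with a Gaussian neighbourhood kernel.

    Uses a deterministic blended batch update per epoch: node weights move
    toward the neighbourhood-weighted mean of their samples by the scheduled
    learning rate, while the Gaussian width decays linearly from half the
    grid diagonal.  Node prediction = mean training p-activity of captured
    compounds; empty nodes inherit from the nearest occupied node.
    """
    spec = spec or ModelSpec("KN")
    rows = spec.get("grid_rows", 10)
    cols_n = spec.get("grid_cols", 10)
    epochs = spec.get("epochs", 100)
    lr0 = spec.get("lr0", 0.5)
    lr1 = spec.get("lr1", 0.01)
    sigma_min = spec.get("sigma_min", 0.5)

    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    scaler = MinMaxScaler().fit(x_train)
    xt = scaler.transform(x_train)
    n_nodes = rows * cols_n
    grid_pos = np.array([(r, c) for r in range(rows) for c in range(cols_n)], dtype=float)
    grid_d2 = ((grid_pos[:, None, :] - grid_pos[None, :, :]) ** 2).sum(axis=2)
    sigma0 = max(np.sqrt(rows**2 + cols_n**2) / 2.0, sigma_min)

    rng = np.random.default_rng(spec.seed)
    weights = rng.uniform(0.0, 1.0, size=(n_nodes, xt.shape[1]))

    def winners_for(x):
        d2 = ((x[:, None, :] - weights[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        sigma = sigma0 + (sigma_min - sigma0) * frac
        lr = lr0 + (lr1 - lr0) * frac
        win = winners_for(xt)
        h = np.exp(-grid_d2[:, win] / (2.0 * sigma * sigma))  # nodes x samples
        mass = h.sum(axis=1)
        target = (h @ xt) / np.where(mass > 0, mass, 1.0)[:, None]
        update = mass > 0
        weights[update] += lr * (target[update] - weights[update])

    win = winners_for(xt)
    node_value = np.full(n_nodes, np.nan)
    for node in range(n_nodes):
        members = win == node
        if members.any():
            node_value[node] = y_train[members].mean()
    occupied = np.nonzero(~np.isnan(node_value))[0]
    if len(occupied) == 0:
        node_value[:] = y_train.mean() if len(y_train) else 0.0
    else:
        for node in np.nonzero(np.isnan(node_value))[0]:
            nearest = occupied[np.argmin(grid_d2[node, occupied])]
            node_value[node] = node_value[nearest]

    predict_fn = KnPredictor(scaler, weights, node_value)
    d = x_train.shape[1]
    cols = tuple(columns) if columns is not None else tuple(map(str, range(d)))
    return TrainedModel(
        method="KN", columns=cols, predict_fn=predict_fn, scaler=scaler,
        state={"weights": weights, "node_value": node_value, "grid": (rows, cols_n)},
    )
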