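"""Feed-forward neural classifier and conventional baselines.

The classifier is a fully-connected network: an input layer sized to the
hybrid feature vector, hidden layers with a configurable activation (tanh by
default), and a 2-unit softmax output under the convention class 0 = hotspot,
class 1 = coldspot.  Training minimizes softmax cross-entropy (plus an L2
penalty) by backpropagation; the default parameter update is Adagrad-scaled
gradient descent with momentum 0.9, with plain SGD-momentum as an option.
Weights use Xavier initialization (zero-mean normal, variance
2 / (fan_in + fan_out)); biases start at zero.  Everything is deterministic
for a fixed seed.

The default architecture (hidden widths 413-318-251-182-96, learning rate
0.1, 1000 full-batch iterations, seed 6) is the tuned configuration for the
430-feature hybrid input; smaller studies should shrink it (see
``DnnConfig.small``).

``run_baseline`` wraps scikit-learn's RBF-kernel SVM, k-nearest-neighbor and
random-forest classifiers behind the same metrics interface for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import DivergenceError, ParameterError, ShapeError

Activation = Literal["tanh", "relu", "sigmoid"]

_EPS = 1e-8


@dataclass(frozen=True)
class DnnConfig:
    """Network architecture and training hyper-parameters."""

    hidden_widths: tuple[int, ...] = (413, 318, 251, 182, 96)
    input_width: Optional[int] = None  # set from the data at training time
    output_width: int = 2
    hidden_activation: Activation = "tanh"
    learning_rate: float = 0.1
    iterations: int = 1000
    momentum: float = 0.9
    seed: int = 6
    updater: Literal["adagrad", "sgd-momentum"] = "adagrad"
    l2: float = 1e-4
    dropout: float = 0.0
    batch_size: Optional[int] = None  # None = full batch

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.hidden_widths) or self.output_width != 2:
            raise ParameterError("widths must be positive; output width must be 2")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ParameterError("learning_rate must be in (0, 1]")
        if not 0.0 <= self.dropout < 1.0:
            raise ParameterError("dropout must be in [0, 1)")
        if self.l2 < 0:
            raise ParameterError("l2 must be >= 0")
        if self.hidden_activation not in ("tanh", "relu", "sigmoid"):
            raise ParameterError(f"unknown activation {self.hidden_activation!r}")

    @classmethod
    def small(cls, **overrides) -> "DnnConfig":
        """A light two-hidden-layer variant for small feature spaces."""
        defaults = dict(hidden_widths=(64, 32), iterations=300)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class TrainedDnn:
    """Layer parameters plus the config and per-iteration training loss."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: DnnConfig
    loss_trace: list[float] = field(default_factory=list)

    @property
    def layer_widths(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]


def _activate(z: np.ndarray, kind: Activation) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(z)
    if kind == "relu":
        return np.maximum(z, 0.0)
    return 1.0 / (1.0 + np.exp(-z))  # sigmoid


def _activate_grad(a: np.ndarray, z: np.ndarray, kind: Activation) -> np.ndarray:
    """Derivative of the activation, written in terms of output a (and z for relu)."""
    if kind == "tanh":
        return 1.0 - a**2
    if kind == "relu":
        return (z > 0).astype(float)
    return a * (1.0 - a)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def init_network(config: DnnConfig) -> TrainedDnn:
    """Xavier-initialized network: W ~ N(0, 2/(fan_in+fan_out)), b = 0."""
    if config.input_width is None:
        raise ParameterError("input_width must be set before initialization")
    widths = [config.input_width, *config.hidden_widths, config.output_width]
    rng = np.random.default_rng(config.seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        std = np.sqrt(2.0 / (fan_in + fan_out))
        weights.append(rng.normal(0.0, std, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return TrainedDnn(weights, biases, config)


def _forward_pass(
    net: TrainedDnn, X: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Return per-layer pre-activations and activations (activations[0] = X)."""
    act = net.config.hidden_activation
    zs: list[np.ndarray] = []
    activations = [X]
    a = X
    n_layers = len(net.weights)
    for li, (W, b) in enumerate(zip(net.weights, net.biases)):
        z = a @ W + b
        zs.append(z)
        a = _softmax(z) if li == n_layers - 1 else _activate(z, act)
        activations.append(a)
    return zs, activations


def forward(net: TrainedDnn, X: np.ndarray) -> np.ndarray:
    """Class probabilities, shape (n, 2); rows sum to 1."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != net.weights[0].shape[0]:
        raise ShapeError(
            f"input width {X.shape[-1] if X.ndim == 2 else '?'} does not match "
            f"network input {net.weights[0].shape[0]}"
        )
    return _forward_pass(net, X)[1][-1]


def predict(net: TrainedDnn, X: np.ndarray) -> np.ndarray:
    """Hard labels (0 = hotspot, 1 = coldspot); a 0.5/0.5 tie resolves to 0."""
    return np.argmax(forward(net, X), axis=1)


def _one_hot(y: np.ndarray) -> np.ndarray:
    Y = np.zeros((len(y), 2))
    Y[np.arange(len(y)), y] = 1.0
    return Y


def loss_and_gradients(
    net: TrainedDnn, X: np.ndarray, y: np.ndarray
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Cross-entropy (+ L2) loss and its gradients w.r.t. every weight and bias.

    Exposed so the analytic gradients can be checked against finite
    differences; dropout is not applied here.
    """
    Y = _one_hot(np.asarray(y, dtype=int))
    n = len(X)
    l2 = net.config.l2
    zs, activations = _forward_pass(net, X)
    probs = activations[-1]
    ce = -np.mean(np.sum(Y * np.log(probs + 1e-300), axis=1))
    loss = ce + 0.5 * l2 * sum(float(np.sum(W**2)) for W in net.weights)

    act = net.config.hidden_activation
    dWs = [np.empty(0)] * len(net.weights)
    dbs = [np.empty(0)] * len(net.biases)
    delta = (probs - Y) / n
    for li in range(len(net.weights) - 1, -1, -1):
        dWs[li] = activations[li].T @ delta + l2 * net.weights[li]
        dbs[li] = delta.sum(axis=0)
        if li > 0:
            delta = (delta @ net.weights[li].T) * _activate_grad(
                activations[li], zs[li - 1], act
            )
    return loss, dWs, dbs


def train_dnn(X: np.ndarray, y: Sequence[int], config: DnnConfig) -> TrainedDnn:
    """Train by backpropagation; deterministic for fixed data, config and seed.

    Full-batch by default; ``batch_size`` enables seeded mini-batch shuffling.
    Raises :class:`DivergenceError` naming the iteration if the loss goes
    non-finite.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ShapeError("X must be 2-D with one label per row")
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ParameterError("need at least 2 samples per class")
    if config.input_width is None:
        config = replace(config, input_width=X.shape[1])
    elif config.input_width != X.shape[1]:
        raise ShapeError(
            f"config input_width {config.input_width} != data width {X.shape[1]}"
        )
    net = init_network(config)
    rng = np.random.default_rng(config.seed + 1)  # dropout / batch shuffling
    lr, mom = config.learning_rate, config.momentum
    vel_W = [np.zeros_like(W) for W in net.weights]
    vel_b = [np.zeros_like(b) for b in net.biases]
    cache_W = [np.zeros_like(W) for W in net.weights]
    cache_b = [np.zeros_like(b) for b in net.biases]

    n = len(X)
    batch = config.batch_size or n
    for it in range(config.iterations):
        if batch >= n:
            batches = [np.arange(n)]
        else:
            perm = rng.permutation(n)
            batches = [perm[i : i + batch] for i in range(0, n, batch)]
        epoch_loss = 0.0
        for idx in batches:
            Xb, yb = X[idx], y[idx]
            if config.dropout > 0:
                loss, dWs, dbs = _dropout_gradients(net, Xb, yb, rng)
            else:
                loss, dWs, dbs = loss_and_gradients(net, Xb, yb)
            epoch_loss += loss * len(idx) / n
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at iteration {it}")
            for li in range(len(net.weights)):
                for param, grad, vel, cache in (
                    (net.weights[li], dWs[li], vel_W[li], cache_W[li]),
                    (net.biases[li], dbs[li], vel_b[li], cache_b[li]),
                ):
                    if config.updater == "adagrad":
                        cache += grad**2
                        step = lr * grad / (np.sqrt(cache) + _EPS)
                    else:  # sgd-momentum
                        step = lr * grad
                    vel *= mom
                    vel += step
                    param -= vel
        net.loss_trace.append(float(epoch_loss))
    return net


def _dropout_gradients(net, Xb, yb, rng):
    """Gradients with inverted dropout on hidden activations."""
    keep = 1.0 - net.config.dropout
    act = net.config.hidden_activation
    l2 = net.config.l2
    Y = _one_hot(np.asarray(yb, dtype=int))
    n = len(Xb)
    zs, activations, masks = [], [Xb], []
    a = Xb
    n_layers = len(net.weights)
    for li, (W, b) in enumerate(zip(net.weights, net.biases)):
        z = a @ W + b
        zs.append(z)
        if li == n_layers - 1:
            a = _softmax(z)
            masks.append(None)
        else:
            a = _activate(z, act)
            m = (rng.random(a.shape) < keep) / keep
            a = a * m
            masks.append(m)
        activations.append(a)
    probs = activations[-1]
    ce = -np.mean(np.sum(Y * np.log(probs + 1e-300), axis=1))
    loss = ce + 0.5 * l2 * sum(float(np.sum(W**2)) for W in net.weights)
    dWs = [np.empty(0)] * n_layers
    dbs = [np.empty(0)] * n_layers
    delta = (probs - Y) / n
    for li in range(n_layers - 1, -1, -1):
        dWs[li] = activations[li].T @ delta + l2 * net.weights[li]
        dbs[li] = delta.sum(axis=0)
        if li > 0:
            # activations[li] includes the mask; derivative uses pre-mask output
            pre_mask = _activate(zs[li - 1], act)
            delta = (delta @ net.weights[li].T) * masks[li - 1] * _activate_grad(
                pre_mask, zs[li - 1], act
            )
    return loss, dWs, dbs


def save_dnn(net: TrainedDnn, path) -> None:
    """Serialize a trained network (config + arrays) into one .npz archive."""
    import json

    payload = {f"W{i}": W for i, W in enumerate(net.weights)}
    payload.update({f"b{i}": b for i, b in enumerate(net.biases)})
    payload["loss_trace"] = np.asarray(net.loss_trace)
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in
           net.config.__dict__.items()}
    payload["config_json"] = np.array(json.dumps(cfg))
    np.savez(path, **payload)


def load_dnn(path) -> TrainedDnn:
    """Load a network saved by :func:`save_dnn`."""
    import json

    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(str(data["config_json"]))
        cfg["hidden_widths"] = tuple(cfg["hidden_widths"])
        config = DnnConfig(**cfg)
        n_layers = len(config.hidden_widths) + 1
        weights = [data[f"W{i}"] for i in range(n_layers)]
        biases = [data[f"b{i}"] for i in range(n_layers)]
        trace = list(data["loss_trace"])
    return TrainedDnn(weights, biases, config, trace)


# ---------------------------------------------------------------------------
# conventional baselines


@dataclass(frozen=True)
class BaselineSpec:
    """A conventional classifier standing next to the network.

    kinds: ``svm`` (RBF kernel; params C, gamma), ``knn`` (param k),
    ``rf`` (params ntree, mtry).
    """

    kind: Literal["svm", "knn", "rf"]
    params: dict = field(default_factory=dict)

    def build(self, seed: int = 0):
        p = dict(self.params)
        if self.kind == "svm":
            return SVC(
                kernel="rbf",
                C=p.get("C", 1.0),
                gamma=p.get("gamma", "scale"),
                random_state=seed,
            )
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=p.get("k", 5))
        if self.kind == "rf":
            return RandomForestClassifier(
                n_estimators=p.get("ntree", 500),
                max_features=p.get("mtry", "sqrt"),
                random_state=seed,
            )
        raise ParameterError(f"unknown baseline kind {self.kind!r}")


def run_baseline(
    kind: str,
    params: dict,
    X: np.ndarray,
    y: Sequence[int],
    folds: Optional[int] = 10,
    seed: int = 0,
):
    """Cross-validated metrics for a conventional classifier.

    ``folds=None`` evaluates on the training data itself (resubstitution).
    Returns the same Metrics object as the network evaluation path.
    """
    from .evaluation import confusion, compute_metrics  # local import, no cycle
    from sklearn.model_selection import StratifiedKFold

    spec = BaselineSpec(kind=kind, params=params)  # validates kind
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if folds is None:
        clf = spec.build(seed)
        clf.fit(X, y)
        pred = clf.predict(X)
        return compute_metrics(confusion(y, pred))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    truth, preds = [], []
    for train_idx, test_idx in skf.split(X, y):
        mu, sd = X[train_idx].mean(axis=0), X[train_idx].std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        clf = spec.build(seed)
        clf.fit((X[train_idx] - mu) / sd, y[train_idx])
        preds.extend(clf.predict((X[test_idx] - mu) / sd))
        truth.extend(y[test_idx])
    return compute_metrics(confusion(np.array(truth), np.array(preds)))
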