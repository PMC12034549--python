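"""From-scratch backpropagation multilayer perceptron with inverted dropout.

One ``Network`` type serves both ensemble members: the fully connected
network (FCNN, dropout rate 0) and the dropout-regularized network
(dropout rate > 0) share a single code path, so the FCNN is exactly the
degenerate dropout case.

Forward pass: h = f(W1 x + b1), y = f(W2 h + b2) layer by layer.  Loss is
the half squared error E = 1/2 * sum_l (y_l - d_l)^2.  Training is plain
mini-batch gradient descent, w <- w - eta * dE/dw.  Dropout is inverted:
during a training-mode forward each hidden unit is zeroed with
probability p and survivors are scaled by 1/(1-p), so inference applies
no mask and no rescaling.  Dropout touches hidden layers only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .schema import Dataset

__all__ = [
    "Network",
    "TrainConfig",
    "FitResult",
    "ForwardRecord",
    "init_network",
    "forward",
    "loss",
    "backward",
    "sgd_step",
    "train",
    "predict_proba",
    "predict_label",
    "save_network",
    "load_network",
]

_ACTIVATIONS = {
    "sigmoid": (lambda z: 1.0 / (1.0 + np.exp(-z)), lambda a: a * (1.0 - a)),
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
}


@dataclass
class Network:
    """Layer sizes, parameters, activation name and dropout rate.

    ``weights[g]`` has shape (size of layer g+1, size of layer g);
    entry (i, j) connects neuron j of layer g to neuron i of layer g+1.
    ``scaler`` optionally holds per-column (offset, range) applied to
    inputs before the first layer (min-max scaling of integer codes).
    """

    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str = "sigmoid"
    dropout_rate: float = 0.0
    scaler: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if len(self.weights) != len(self.layer_sizes) - 1:
            raise ValueError("one weight matrix per layer transition required")
        for g, (W, b) in enumerate(zip(self.weights, self.biases)):
            want = (self.layer_sizes[g + 1], self.layer_sizes[g])
            if W.shape != want or b.shape != (want[0],):
                raise ValueError(f"layer {g}: shape mismatch {W.shape} vs {want}")
            if not (np.isfinite(W).all() and np.isfinite(b).all()):
                raise ValueError(f"layer {g}: non-finite parameters")

    def copy(self) -> "Network":
        return Network(
            list(self.layer_sizes),
            [W.copy() for W in self.weights],
            [b.copy() for b in self.biases],
            self.activation,
            self.dropout_rate,
            None if self.scaler is None else (self.scaler[0].copy(), self.scaler[1].copy()),
        )


@dataclass(frozen=True)
class TrainConfig:
    """Gradient-descent hyperparameters.

    Defaults: one hidden layer of 16 sigmoid units, eta = 0.1, 200
    epochs, mini-batches of 32, uniform init in [-0.1, 0.1].  ``scale``
    turns on min-max scaling of the integer codes to [0, 1] using the
    schema's code ranges (data-independent, so train and test agree).
    """

    learning_rate: float = 0.1
    epochs: int = 200
    batch_size: int = 32
    init_scale: float = 0.1
    seed: int = 0
    hidden_sizes: tuple[int, ...] = (16,)
    activation: str = "sigmoid"
    scale: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.init_scale <= 0:
            raise ValueError("init_scale must be > 0")


@dataclass(frozen=True)
class FitResult:
    network: Network
    training_accuracy: float
    loss_history: np.ndarray  # per-epoch mean loss


@dataclass(frozen=True)
class ForwardRecord:
    """Everything backward needs: per-layer activations (a[0] is the
    scaled input), pre-activations z, and the dropout masks applied
    (None per layer when no unit was dropped)."""

    activations: list[np.ndarray]
    pre_activations: list[np.ndarray]
    masks: list[np.ndarray | None]


def init_network(
    n_inputs: int,
    cfg: TrainConfig,
    dropout_rate: float = 0.0,
    n_outputs: int = 1,
) -> Network:
    rng = np.random.default_rng(cfg.seed)
    sizes = [n_inputs, *cfg.hidden_sizes, n_outputs]
    weights = [
        rng.uniform(-cfg.init_scale, cfg.init_scale, size=(sizes[g + 1], sizes[g]))
        for g in range(len(sizes) - 1)
    ]
    biases = [np.zeros(sizes[g + 1]) for g in range(len(sizes) - 1)]
    return Network(sizes, weights, biases, cfg.activation, dropout_rate)


def _apply_scaler(net: Network, X: np.ndarray) -> np.ndarray:
    if net.scaler is None:
        return X.astype(float)
    offset, span = net.scaler
    return (X.astype(float) - offset) / span


def forward(
    net: Network,
    x: np.ndarray,
    mode: str = "infer",
    rng: np.random.Generator | None = None,
) -> ForwardRecord:
    """Propagate a batch (or single record) through the network.

    In train mode with dropout rate p > 0, each hidden unit is zeroed
    with probability p and survivors scaled by 1/(1-p); infer mode is
    mask-free.  An rng is required exactly when masks are drawn.
    """
    if mode not in ("train", "infer"):
        raise ValueError("mode must be 'train' or 'infer'")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != net.layer_sizes[0]:
        raise ValueError(f"input width {x.shape[1]} != network input size {net.layer_sizes[0]}")
    p = net.dropout_rate
    dropping = mode == "train" and p > 0.0
    if dropping and rng is None:
        raise ValueError("rng required for train-mode forward with dropout")

    f, _ = _ACTIVATIONS[net.activation]
    a = _apply_scaler(net, x)
    activations, pre_activations, masks = [a], [], []
    n_layers = len(net.weights)
    for g, (W, b) in enumerate(zip(net.weights, net.biases)):
        z = a @ W.T + b
        a = f(z)
        if not np.isfinite(a).all():
            raise FloatingPointError(f"non-finite activation in layer {g + 1}")
        mask = None
        if dropping and g < n_layers - 1:  # hidden layers only
            mask = (rng.random(a.shape) >= p).astype(float) / (1.0 - p)
            a = a * mask
        pre_activations.append(z)
        activations.append(a)
        masks.append(mask)
    return ForwardRecord(activations, pre_activations, masks)


def loss(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Half squared error E = 1/2 * sum (y - d)^2 over output units."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("predicted/actual length mismatch")
    return float(0.5 * np.sum((predicted - actual) ** 2))


def backward(
    net: Network, record: ForwardRecord, d: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Gradients of the (batch-summed) half-squared error by the chain rule.

    Reuses the masks stored in the forward record, so units dropped on
    the forward pass contribute zero gradient through their weights.
    """
    d = np.atleast_2d(np.asarray(d, dtype=float))
    out = record.activations[-1]
    if out.shape != d.shape:
        raise ValueError(f"target shape {d.shape} != output shape {out.shape}")
    _, fprime = _ACTIVATIONS[net.activation]

    grads_W: list[np.ndarray] = [None] * len(net.weights)  # type: ignore[list-item]
    grads_b: list[np.ndarray] = [None] * len(net.weights)  # type: ignore[list-item]
    # delta = dE/dz at the current layer
    delta = (out - d) * fprime(out)
    for g in range(len(net.weights) - 1, -1, -1):
        a_prev = record.activations[g]
        grads_W[g] = delta.T @ a_prev
        grads_b[g] = delta.sum(axis=0)
        if g > 0:
            mask = record.masks[g - 1]
            back = delta @ net.weights[g]
            if mask is not None:
                back = back * mask
            # activations[g] stores the post-mask value; f'(a) needs the
            # pre-mask activation f(z)
            f, _ = _ACTIVATIONS[net.activation]
            a_unmasked = f(record.pre_activations[g - 1])
            delta = back * fprime(a_unmasked)
    return grads_W, grads_b


def sgd_step(
    net: Network,
    grads: tuple[list[np.ndarray], list[np.ndarray]],
    learning_rate: float,
) -> Network:
    """One gradient-descent update, returning a new network."""
    if learning_rate <= 0:
        raise ValueError("learning rate must be > 0")
    grads_W, grads_b = grads
    new = net.copy()
    for g in range(len(new.weights)):
        new.weights[g] -= learning_rate * grads_W[g]
        new.biases[g] -= learning_rate * grads_b[g]
        if not (np.isfinite(new.weights[g]).all() and np.isfinite(new.biases[g]).all()):
            raise FloatingPointError(f"non-finite update in layer {g}")
    return new


def _schema_scaler(data: Dataset) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([min(c) for c in data.schema.feature_codes], dtype=float)
    hi = np.array([max(c) for c in data.schema.feature_codes], dtype=float)
    span = np.where(hi > lo, hi - lo, 1.0)
    return lo, span


def train(net: Network, data: Dataset, cfg: TrainConfig) -> FitResult:
    """Mini-batch gradient descent; deterministic given cfg.seed.

    Shuffles each epoch, records the per-epoch mean loss, and reports
    the final training-set accuracy (the quantity the ensemble weights
    consume).
    """
    if data.n < 1:
        raise ValueError("empty training set")
    net = net.copy()
    if cfg.scale and net.scaler is None:
        net.scaler = _schema_scaler(data)
    X = data.X.astype(float)
    y = data.y.astype(float).reshape(-1, 1)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7EA1]))
    history = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        order = rng.permutation(data.n)
        total = 0.0
        for start in range(0, data.n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            rec = forward(net, X[idx], mode="train", rng=rng)
            total += loss(rec.activations[-1].ravel(), y[idx].ravel())
            grads = backward(net, rec, y[idx])
            try:
                net = sgd_step(net, grads, cfg.learning_rate)
            except FloatingPointError as exc:
                raise FloatingPointError(f"divergence at epoch {epoch}: {exc}") from exc
        history[epoch] = total / data.n
        if not np.isfinite(history[epoch]):
            raise FloatingPointError(f"divergence at epoch {epoch}: non-finite loss")
    acc = float(np.mean(predict_label(net, data.X) == data.y))
    return FitResult(network=net, training_accuracy=acc, loss_history=history)


def predict_proba(net: Network, X: np.ndarray) -> np.ndarray:
    """Positive-class probability per record (single sigmoid output)."""
    if net.layer_sizes[-1] != 1:
        raise ValueError("predict_proba requires a single output unit")
    rec = forward(net, np.asarray(X), mode="infer")
    return rec.activations[-1].ravel()


def predict_label(net: Network, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary labels; a probability exactly at threshold predicts positive
    (screening favors recall)."""
    return (predict_proba(net, X) >= threshold).astype(np.int64)


def save_network(net: Network, path) -> None:
    """Serialize to JSON; float64 repr round-trips bit-exactly."""
    payload = {
        "layer_sizes": net.layer_sizes,
        "activation": net.activation,
        "dropout_rate": net.dropout_rate,
        "weights": [W.tolist() for W in net.weights],
        "biases": [b.tolist() for b in net.biases],
        "scaler": None if net.scaler is None else [s.tolist() for s in net.scaler],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_network(path) -> Network:
    with open(path) as fh:
        payload = json.load(fh)
    scaler = payload["scaler"]
    return Network(
        layer_sizes=list(payload["layer_sizes"]),
        weights=[np.array(W, dtype=float) for W in payload["weights"]],
        biases=[np.array(b, dtype=float) for b in payload["biases"]],
        activation=payload["activation"],
        dropout_rate=float(payload["dropout_rate"]),
        scaler=None if scaler is None else (np.array(scaler[0]), np.array(scaler[1])),
    )
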