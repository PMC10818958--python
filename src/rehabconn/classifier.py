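"""Small feed-forward classifier trained with SGD + momentum.

Architecture: input -> 10 -> 5 -> 2 fully connected layers with leaky-ReLU
(slope 0.01) between them and a softmax output over the two classes
(before / after rehabilitation).  Training uses mini-batch stochastic
gradient descent with a classical momentum (velocity) term on the
cross-entropy loss, shuffling the data each epoch.  Everything is plain
NumPy so gradients can be checked against finite differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

CLASS_ORDER = ("before", "after")
HIDDEN = (10, 5, 2)


@dataclass
class MLPParams:
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    leaky_slope: float = 0.01
    init_seed: int = 0

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0],) + tuple(w.shape[1] for w in self.weights)


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    momentum: float = 0.9
    max_epochs: int = 40
    batch_size: int = 10
    shuffle_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")


def init_mlp(input_dim: int, seed: int = 0, leaky_slope: float = 0.01) -> MLPParams:
    """Fan-in-scaled uniform weight init, zero biases, deterministic per seed."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = (input_dim,) + HIDDEN
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = np.sqrt(6.0 / fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPParams(weights=weights, biases=biases, leaky_slope=leaky_slope, init_seed=seed)


def _leaky(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, z, slope * z)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_cache(p: MLPParams, x: np.ndarray):
    acts = [x]
    pre = []
    h = x
    last = len(p.weights) - 1
    for k, (w, b) in enumerate(zip(p.weights, p.biases)):
        z = h @ w + b
        pre.append(z)
        h = z if k == last else _leaky(z, p.leaky_slope)
        acts.append(h)
    return _softmax(acts[-1]), pre, acts


def forward(p: MLPParams, batch: np.ndarray) -> np.ndarray:
    """Class probabilities, one row per example, rows summing to 1."""
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if not np.all(np.isfinite(batch)):
        raise ValueError("non-finite input to forward pass")
    if batch.shape[1] != p.weights[0].shape[0]:
        raise ValueError(
            f"input width {batch.shape[1]} != model input_dim {p.weights[0].shape[0]}"
        )
    probs, _, _ = _forward_cache(p, batch)
    return probs


def loss_and_grads(p: MLPParams, x: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its analytic gradients for a batch.

    ``y`` holds class indices (0 = before, 1 = after).
    """
    n = x.shape[0]
    probs, pre, acts = _forward_cache(p, x)
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(n), y] + eps)))
    delta = probs.copy()
    delta[np.arange(n), y] -= 1.0
    delta /= n
    grads_w, grads_b = [None] * len(p.weights), [None] * len(p.weights)
    for k in range(len(p.weights) - 1, -1, -1):
        grads_w[k] = acts[k].T @ delta
        grads_b[k] = delta.sum(axis=0)
        if k > 0:
            delta = delta @ p.weights[k].T
            delta *= np.where(pre[k - 1] > 0, 1.0, p.leaky_slope)
    return loss, grads_w, grads_b


def train_sgdm(p: MLPParams, x: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> MLPParams:
    """Mini-batch SGD with momentum: v <- mu v - eta grad; w <- w + v.

    Runs exactly ceil(n / batch_size) * max_epochs updates; deterministic
    given the config seed.  Raises if the loss diverges to NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 examples of each class to train")
    rng = np.random.default_rng(cfg.seed)
    weights = [w.copy() for w in p.weights]
    biases = [b.copy() for b in p.biases]
    vel_w = [np.zeros_like(w) for w in weights]
    vel_b = [np.zeros_like(b) for b in biases]
    cur = MLPParams(weights, biases, p.leaky_slope, p.init_seed)
    n = x.shape[0]
    order = np.arange(n)
    for _epoch in range(cfg.max_epochs):
        if cfg.shuffle_each_epoch:
            order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, gw, gb = loss_and_grads(cur, x[idx], y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    "training diverged (loss is not finite); lower the learning rate"
                )
            for k in range(len(weights)):
                vel_w[k] = cfg.momentum * vel_w[k] - cfg.learning_rate * gw[k]
                vel_b[k] = cfg.momentum * vel_b[k] - cfg.learning_rate * gb[k]
                weights[k] += vel_w[k]
                biases[k] += vel_b[k]
    return cur


def predict(p: MLPParams, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and the probability of the "after" class.

    An exact 0.5/0.5 tie resolves to "before" (class index 0) and is logged.
    """
    probs = forward(p, x)
    ties = probs[:, 0] == probs[:, 1]
    if ties.any():
        logger.info("%d exact probability ties resolved to 'before'", int(ties.sum()))
    labels = np.where(probs[:, 1] > probs[:, 0], CLASS_ORDER[1], CLASS_ORDER[0])
    return labels, probs[:, 1]


@dataclass
class Standardizer:
    """Per-column z-scoring with statistics frozen on the training fold."""

    mean: np.ndarray
    sd: np.ndarray

    @staticmethod
    def fit(x: np.ndarray) -> "Standardizer":
        sd = x.std(axis=0)
        return Standardizer(mean=x.mean(axis=0), sd=np.where(sd > 0, sd, 1.0))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd
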