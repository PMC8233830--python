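"""Single-hidden-layer neural network trained with Adam, in plain numpy.

The classifier maps a concatenated stance profile (1000 points per muscle)
to one of the five walking environments.  Architecture: input -> fully
connected hidden layer with ReLU -> fully connected output layer of 5
logits; the loss is mean softmax cross-entropy with logits, minimized by
Adam.  The network is small enough that a dependency-free implementation
is both fastest to audit and exactly reproducible from a seed.

The study this pipeline follows reports none of the hyperparameters
(hidden width, learning rate, epochs, batch size); the defaults below are
package choices, exposed in :class:`AnnConfig` and echoed into evaluation
reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss; try a lower learning rate."""


@dataclass
class AnnConfig:
    hidden: int = 100
    learning_rate: float = 1e-3
    epochs: int = 300
    batch_size: int = 32
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("hidden", "learning_rate", "epochs", "batch_size", "seed",
                 "beta1", "beta2", "eps")}


@dataclass
class AnnModel:
    """Trained weights plus the config and loss trace that produced them."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    classes: np.ndarray
    config: AnnConfig = field(default_factory=AnnConfig)
    loss_trace: list[float] = field(default_factory=list)

    @property
    def input_width(self) -> int:
        return self.W1.shape[0]

    def logits(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.input_width:
            raise ValueError(
                f"profile width {X.shape[1]} does not match model input "
                f"width {self.input_width}")
        H = np.maximum(X @ self.W1 + self.b1, 0.0)
        return H @ self.W2 + self.b2


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict_proba(model: AnnModel, profiles) -> np.ndarray:
    """Per-class probabilities (rows sum to 1)."""
    return softmax(model.logits(profiles))


def predict(model: AnnModel, profiles) -> np.ndarray:
    """Class labels; argmax ties break toward the lowest label index."""
    p = predict_proba(model, profiles)
    return model.classes[np.argmax(p, axis=1)]


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(classes, y)
    if not np.array_equal(classes[idx], y):
        raise ValueError("labels outside the training class set")
    out = np.zeros((y.shape[0], classes.shape[0]))
    out[np.arange(y.shape[0]), idx] = 1.0
    return out


def loss_and_grads(params: dict, X: np.ndarray, Y: np.ndarray
                   ) -> tuple[float, dict]:
    """Mean softmax cross-entropy and its analytic gradients.

    ``params`` holds W1, b1, W2, b2; ``Y`` is one-hot.  Exposed separately
    so the gradients can be checked against finite differences.
    """
    W1, b1, W2, b2 = params["W1"], params["b1"], params["W2"], params["b2"]
    A = X @ W1 + b1
    H = np.maximum(A, 0.0)
    logits = H @ W2 + b2
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = X.shape[0]
    loss = -float((Y * logp).sum()) / n

    dlogits = (np.exp(logp) - Y) / n
    grads = {
        "W2": H.T @ dlogits,
        "b2": dlogits.sum(axis=0),
    }
    dH = dlogits @ W2.T
    dA = dH * (A > 0)
    grads["W1"] = X.T @ dA
    grads["b1"] = dA.sum(axis=0)
    return loss, grads


def init_params(input_width: int, hidden: int, n_classes: int,
                rng: np.random.Generator) -> dict:
    """He-uniform initialization for both layers; zero biases."""
    lim1 = np.sqrt(6.0 / input_width)
    lim2 = np.sqrt(6.0 / hidden)
    return {
        "W1": rng.uniform(-lim1, lim1, size=(input_width, hidden)),
        "b1": np.zeros(hidden),
        "W2": rng.uniform(-lim2, lim2, size=(hidden, n_classes)),
        "b2": np.zeros(n_classes),
    }


def train_ann(X, y, config: AnnConfig | None = None) -> AnnModel:
    """Train the network by mini-batch Adam; deterministic given the seed."""
    config = config or AnnConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_samples, width) aligned with y")
    classes = np.unique(y)
    if classes.shape[0] < 2:
        raise ValueError("training set must contain at least 2 classes")
    Y = _one_hot(y, classes)

    rng = np.random.default_rng(config.seed)
    params = init_params(X.shape[1], config.hidden, classes.shape[0], rng)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(w) for k, w in params.items()}
    t = 0
    trace: list[float] = []
    n = X.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            loss, grads = loss_and_grads(params, X[batch], Y[batch])
            if not np.isfinite(loss):
                raise DivergenceError(
                    "non-finite training loss; lower the learning rate")
            epoch_loss += loss * batch.shape[0]
            t += 1
            for k in params:
                m[k] = config.beta1 * m[k] + (1 - config.beta1) * grads[k]
                v[k] = config.beta2 * v[k] + (1 - config.beta2) * grads[k] ** 2
                m_hat = m[k] / (1 - config.beta1 ** t)
                v_hat = v[k] / (1 - config.beta2 ** t)
                params[k] -= (config.learning_rate * m_hat
                              / (np.sqrt(v_hat) + config.eps))
        trace.append(epoch_loss / n)
    return AnnModel(W1=params["W1"], b1=params["b1"], W2=params["W2"],
                    b2=params["b2"], classes=classes, config=config,
                    loss_trace=trace)
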