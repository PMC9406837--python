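"""Classification heads: a linear SVM and a shallow neural network.

The SVM head receives PCA-reduced deep features and finds the
maximum-margin linear separator (hinge loss, regularization constant C);
features are standardized inside the model so callers never handle
scaling. The ANN head is a fully connected network — one hidden layer of
15 tanh units by default, a 2-unit softmax output — trained with plain
full-batch gradient descent on the cross-entropy (MSE selectable), with
early stopping after `patience` consecutive validation checks without
improvement (default 6) and restoration of the best-validation weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .errors import TrainingDivergenceError

__all__ = [
    "SvmModel", "train_linear_svm", "svm_predict", "svm_decision_scores",
    "TrainConfig", "AnnModel", "train_ann", "ann_predict",
]

POSITIVE_LABEL = "malignant"


def _binary_classes(y: Sequence) -> tuple[list, np.ndarray]:
    """Map labels to {0, 1} with a stable convention: 'malignant' (or the
    lexicographically larger label) is the positive class 1."""
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    if POSITIVE_LABEL in classes:
        neg = [c for c in classes if c != POSITIVE_LABEL][0]
        ordered = [neg, POSITIVE_LABEL]
    else:
        ordered = classes
    index = {c: i for i, c in enumerate(ordered)}
    return ordered, np.array([index[v] for v in y])


# --- SVM -------------------------------------------------------------------

@dataclass
class SvmModel:
    weights: np.ndarray
    bias: float
    C: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    classes: list


def train_linear_svm(X: np.ndarray, y: Sequence, C: float = 1.0) -> SvmModel:
    """Hard/soft maximum-margin linear separator on standardized features."""
    X = np.asarray(X, dtype=np.float64)
    classes, y01 = _binary_classes(y)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    svc = SVC(kernel="linear", C=C)
    svc.fit(Xs, y01)
    return SvmModel(
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        C=C,
        feature_mean=mean,
        feature_scale=scale,
        classes=classes,
    )


def svm_decision_scores(model: SvmModel, X: np.ndarray) -> np.ndarray:
    """Signed affine score; positive means the positive class."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[0] and X.shape[1] != model.weights.size:
        raise ValueError(f"feature width {X.shape[1]} != model width {model.weights.size}")
    if X.shape[0] == 0:
        return np.zeros(0)
    Xs = (X - model.feature_mean) / model.feature_scale
    return Xs @ model.weights + model.bias


def svm_predict(model: SvmModel, X: np.ndarray) -> list:
    """Labels from the sign of the score; a score of exactly 0 is
    assigned to the positive class."""
    scores = svm_decision_scores(model, X)
    return [model.classes[1] if s >= 0 else model.classes[0] for s in scores]


# --- ANN -------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 300
    patience: int = 6
    learning_rate: float = 0.01
    seed: int = 0
    hidden_layout: tuple[int, ...] = (15,)
    loss: str = "cross_entropy"     # or "mse"

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.loss not in ("cross_entropy", "mse"):
            raise ValueError("loss must be 'cross_entropy' or 'mse'")


@dataclass
class AnnModel:
    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    classes: list
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    grad_norm: list[float] = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1


def _forward(weights, biases, X):
    """Returns (softmax probabilities, list of hidden activations)."""
    a = X
    hidden = []
    for W, b in zip(weights[:-1], biases[:-1]):
        a = np.tanh(a @ W + b)
        hidden.append(a)
    z = a @ weights[-1] + biases[-1]
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True), hidden


def _loss(probs, onehot, kind):
    if kind == "mse":
        return float(((probs - onehot) ** 2).mean())
    eps = 1e-12
    return float(-(onehot * np.log(probs + eps)).sum(axis=1).mean())


def train_ann(X: np.ndarray, y: Sequence, cfg: TrainConfig,
              X_val: np.ndarray, y_val: Sequence) -> AnnModel:
    """Full-batch gradient descent with validation-based early stopping.

    Tracks per-epoch training loss, validation loss and gradient norm.
    Training stops after `cfg.patience` consecutive epochs without a
    strict validation-loss improvement ("patience") or at
    `cfg.max_epochs` ("max_epochs"); the best-validation weights are
    restored either way. A non-finite loss raises
    :class:`TrainingDivergenceError` with the epoch number.
    """
    X = np.asarray(X, dtype=np.float64)
    Xv = np.asarray(X_val, dtype=np.float64)
    if Xv.shape[0] == 0:
        raise ValueError("validation set must be non-empty")
    classes, y01 = _binary_classes(y)
    _, yv01 = _binary_classes(list(y) + list(y_val))
    yv01 = yv01[len(y):]

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    Xvs = (Xv - mean) / scale

    onehot = np.eye(2)[y01]
    onehot_val = np.eye(2)[yv01]

    sizes = [X.shape[1], *cfg.hidden_layout, 2]
    rng = np.random.default_rng(cfg.seed)
    weights = [rng.standard_normal((sizes[i], sizes[i + 1])) / np.sqrt(sizes[i])
               for i in range(len(sizes) - 1)]
    biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    model = AnnModel(layer_sizes=sizes, weights=weights, biases=biases,
                     feature_mean=mean, feature_scale=scale, classes=classes)
    best_val = np.inf
    best_state = None
    bad_checks = 0
    n = Xs.shape[0]

    for epoch in range(cfg.max_epochs):
        probs, hidden = _forward(weights, biases, Xs)
        loss = _loss(probs, onehot, cfg.loss)
        if not np.isfinite(loss):
            raise TrainingDivergenceError(epoch)

        # backprop; for both losses the output delta is proportional to
        # (probs - onehot) through the softmax
        if cfg.loss == "cross_entropy":
            delta = (probs - onehot) / n
        else:
            # d/dz of mean squared error through softmax
            g = 2.0 * (probs - onehot) / (n * 2)
            delta = probs * (g - (g * probs).sum(axis=1, keepdims=True))
        grads_W = []
        grads_b = []
        activations = [Xs, *hidden]
        for layer in range(len(weights) - 1, -1, -1):
            a_prev = activations[layer]
            grads_W.insert(0, a_prev.T @ delta)
            grads_b.insert(0, delta.sum(axis=0))
            if layer > 0:
                delta = (delta @ weights[layer].T) * (1.0 - activations[layer] ** 2)
        gnorm = float(np.sqrt(sum((g ** 2).sum() for g in grads_W + grads_b)))

        for layer in range(len(weights)):
            weights[layer] -= cfg.learning_rate * grads_W[layer]
            biases[layer] -= cfg.learning_rate * grads_b[layer]

        val_probs, _ = _forward(weights, biases, Xvs)
        vloss = _loss(val_probs, onehot_val, cfg.loss)
        if not np.isfinite(vloss):
            raise TrainingDivergenceError(epoch)

        model.train_loss.append(loss)
        model.val_loss.append(vloss)
        model.grad_norm.append(gnorm)

        if vloss < best_val:
            best_val = vloss
            best_state = ([W.copy() for W in weights], [b.copy() for b in biases])
            model.best_epoch = epoch
            bad_checks = 0
        else:
            bad_checks += 1
            if bad_checks >= cfg.patience:
                model.stop_reason = "patience"
                break
    if not model.stop_reason:
        model.stop_reason = "max_epochs"
    if best_state is not None:
        model.weights, model.biases = best_state
    return model


def ann_predict(model: AnnModel, X: np.ndarray) -> tuple[list, np.ndarray]:
    """(labels, n×2 softmax scores); label = argmax class."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.layer_sizes[0]:
        raise ValueError(f"feature width {X.shape[1]} != model input {model.layer_sizes[0]}")
    Xs = (X - model.feature_mean) / model.feature_scale
    probs, _ = _forward(model.weights, model.biases, Xs)
    labels = [model.classes[i] for i in probs.argmax(axis=1)]
    return labels, probs
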