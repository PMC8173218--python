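"""Transfer-learning heads and the face-inversion contrast.

A frozen network's layer output is read out by a two-layer head
(fully connected sigmoid hidden layer, softmax output) trained with
minibatch stochastic gradient descent on cross-entropy; accuracy on
held-out features measures how linearly accessible the task is in the
frozen representation.  The inversion contrast compares the selected
channels' mean activation to upright versus vertically flipped stimuli
with a paired two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import PairedTResult, paired_t

__all__ = [
    "TransferHeadSpec",
    "TransferHeadResult",
    "train_head",
    "invert_images",
    "InversionContrast",
    "inversion_contrast",
    "chance_level",
]


@dataclass(frozen=True)
class TransferHeadSpec:
    """Two-layer readout head: input -> sigmoid hidden -> softmax classes."""

    input_dim: int
    n_classes: int
    hidden_dim: int = 4096
    epochs: int = 90
    learning_rate: float = 0.1
    batch_size: int = 32

    def __post_init__(self):
        if min(self.input_dim, self.n_classes, self.hidden_dim) < 1:
            raise ValueError("dimensions must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def chance_level(n_classes: int) -> float:
    """Chance accuracy (fraction) of an n-way classifier."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    return 1.0 / n_classes


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class TransferHeadResult:
    """Trained head weights plus evaluation accuracies."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    classes: np.ndarray
    loss_history: np.ndarray
    accuracy: float | None = None
    per_class_accuracy: dict = field(default_factory=dict)

    def predict(self, features) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        h = _sigmoid(X @ self.W1 + self.b1)
        idx = np.argmax(h @ self.W2 + self.b2, axis=1)
        return self.classes[idx]

    def evaluate(self, features, labels) -> tuple[float, dict]:
        pred = self.predict(features)
        labels = np.asarray(labels)
        acc = float((pred == labels).mean())
        per_class = {}
        for k in self.classes:
            mask = labels == k
            if mask.any():
                per_class[k] = float((pred[mask] == k).mean())
        return acc, per_class


def train_head(features, labels, spec: TransferHeadSpec, seed: int,
               eval_features=None, eval_labels=None) -> TransferHeadResult:
    """Train the two-layer head by minibatch SGD on cross-entropy.

    Weights are initialized from a uniform distribution scaled by fan-in;
    identical (features, labels, spec, seed) give identical results.  If
    evaluation features are supplied, overall and per-class accuracy on
    them are recorded.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be sample x input_dim with one label each")
    if X.shape[1] != spec.input_dim:
        raise ValueError(f"feature dim {X.shape[1]} != spec.input_dim {spec.input_dim}")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    if classes.size != spec.n_classes:
        raise ValueError(
            f"{classes.size} classes present in training labels but spec expects "
            f"{spec.n_classes}; every class must appear in training"
        )
    y_idx = np.searchsorted(classes, y)
    rng = np.random.default_rng(seed)
    lim1 = 1.0 / np.sqrt(spec.input_dim)
    lim2 = 1.0 / np.sqrt(spec.hidden_dim)
    W1 = rng.uniform(-lim1, lim1, size=(spec.input_dim, spec.hidden_dim))
    b1 = np.zeros(spec.hidden_dim)
    W2 = rng.uniform(-lim2, lim2, size=(spec.hidden_dim, spec.n_classes))
    b2 = np.zeros(spec.n_classes)
    n = X.shape[0]
    eye = np.eye(spec.n_classes)
    losses = np.empty(spec.epochs)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, tb = X[idx], eye[y_idx[idx]]
            h = _sigmoid(xb @ W1 + b1)
            p = _softmax(h @ W2 + b2)
            total += -float(np.log(np.clip(p[np.arange(len(idx)), y_idx[idx]],
                                           1e-12, None)).sum())
            # backprop
            dlogits = (p - tb) / len(idx)
            dW2 = h.T @ dlogits
            db2 = dlogits.sum(0)
            dh = dlogits @ W2.T * h * (1 - h)
            dW1 = xb.T @ dh
            db1 = dh.sum(0)
            lr = spec.learning_rate
            W1 -= lr * dW1
            b1 -= lr * db1
            W2 -= lr * dW2
            b2 -= lr * db2
        losses[epoch] = total / n
    result = TransferHeadResult(W1, b1, W2, b2, classes, losses)
    if eval_features is not None:
        result.accuracy, result.per_class_accuracy = result.evaluate(
            eval_features, eval_labels
        )
    return result


def invert_images(images) -> np.ndarray:
    """Vertically flip images (row order reversed about the horizontal axis).

    Images are ``(..., H, W)`` arrays (grayscale or channel-first); the
    second-to-last axis is the row axis.  Double inversion is the identity.
    """
    arr = np.asarray(images)
    if arr.ndim < 2:
        raise ValueError("images must have at least 2 dimensions (H, W)")
    return arr[..., ::-1, :].copy()


@dataclass
class InversionContrast:
    """Upright-vs-inverted activation contrast over the selected channels."""

    upright_means: np.ndarray
    inverted_means: np.ndarray
    mean_diff: float
    test: PairedTResult
    channels: tuple

    def summary(self) -> dict:
        return {
            "channels": [int(c) for c in self.channels],
            "mean_upright": float(self.upright_means.mean()),
            "mean_inverted": float(self.inverted_means.mean()),
            "mean_diff": self.mean_diff,
            "t": self.test.t, "df": self.test.df, "p": self.test.p,
            "cohen_d": self.test.cohen_d,
        }


def inversion_contrast(upright_acts, inverted_acts, channels) -> InversionContrast:
    """Paired contrast of mean activation to upright vs inverted stimuli.

    ``upright_acts``/``inverted_acts`` are image x channel x h x w tensors
    with images paired by position; per image, activation is averaged over
    the selected channels and space, and the two series are compared with
    a paired two-tailed t-test.
    """
    up = np.asarray(upright_acts, dtype=float)
    inv = np.asarray(inverted_acts, dtype=float)
    if up.shape != inv.shape:
        raise ValueError("upright and inverted sets must be paired (same shape)")
    if up.ndim != 4:
        raise ValueError("activations must be image x channel x h x w")
    ch = np.asarray(list(channels), dtype=int)
    if ch.size == 0:
        raise ValueError("need at least one channel")
    um = up[:, ch].mean(axis=(1, 2, 3))
    im = inv[:, ch].mean(axis=(1, 2, 3))
    test = paired_t(um, im)
    return InversionContrast(um, im, float(um.mean() - im.mean()), test,
                             tuple(int(c) for c in ch))
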