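"""Single-hidden-layer feed-forward network for panel classification.

The classifier trained inside every cross-validation repetition and every
ensemble-vote iteration: features standardized on the learner set, one
logistic hidden layer, softmax output, multinomial cross-entropy with an L2
weight penalty, optimized by full-batch gradient descent for a fixed epoch
budget. Training is fully deterministic given the data and the seed — no
early stopping, no stochastic minibatching — which is what makes the
repeated-subsampling schemes built on top of it reproducible.

Because the surrounding pipeline trains the same tiny architecture thousands
of times on different subsamples, the module exposes a batched engine that
carries B independent networks through the identical arithmetic in stacked
(B, n, p) arrays. A single fit is the B = 1 case of the same code path, so
the two are equivalent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.special import expit

from .config import NNConfig

__all__ = ["SingleLayerNetClassifier", "train_nn", "predict_nn", "BatchedNets"]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def _init_weights(rng: np.random.Generator, p: int, h: int, k: int,
                  scale: float) -> Tuple[np.ndarray, ...]:
    """Uniform(-scale, scale) draws in a fixed order (W1, b1, W2, b2)."""
    w1 = rng.uniform(-scale, scale, size=(p, h))
    b1 = rng.uniform(-scale, scale, size=(h,))
    w2 = rng.uniform(-scale, scale, size=(h, k))
    b2 = rng.uniform(-scale, scale, size=(k,))
    return w1, b1, w2, b2


@dataclass
class BatchedNets:
    """B independently trained networks over stacked arrays.

    mean_/scale_ are the per-network standardizers (B, 1, p); weight arrays
    are (B, p, h), (B, 1, h), (B, h, k), (B, 1, k).
    """

    mean_: np.ndarray
    scale_: np.ndarray
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    classes_: np.ndarray

    @property
    def n_nets(self) -> int:
        return self.w1.shape[0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """X: (B, m, p) per-network test blocks -> (B, m, k) probabilities."""
        if X.ndim != 3 or X.shape[2] != self.w1.shape[1]:
            raise ValueError(
                f"expected (B, m, {self.w1.shape[1]}) features, got {X.shape}"
            )
        Xs = (X - self.mean_) / self.scale_
        hidden = expit(Xs @ self.w1 + self.b1)
        return _softmax(hidden @ self.w2 + self.b2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=-1)]


def train_batched(
    X: np.ndarray,
    Y: np.ndarray,
    classes: np.ndarray,
    config: NNConfig,
    init_seeds: Sequence[int],
) -> BatchedNets:
    """Train B networks simultaneously.

    X: (B, n, p) learner features per network; Y: (B, n, k) one-hot learner
    labels; init_seeds: one RNG seed per network for the weight draws.

    The epoch loop works on augmented arrays (bias folded into an extra
    ones-column) with preallocated buffers: this code path is executed tens
    of thousands of times by the search and voting stages, so avoiding
    per-epoch allocations matters. The weight-decay penalty applies to the
    weight matrices only, never the biases.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    B, n, p = X.shape
    k = Y.shape[2]
    if len(init_seeds) != B:
        raise ValueError("need exactly one init seed per network")
    h = config.hidden_units

    mean = X.mean(axis=1, keepdims=True)
    scale = X.std(axis=1, ddof=0, keepdims=True)
    scale = np.where(scale == 0.0, 1.0, scale)  # zero-variance feature: scale 1

    # augmented learner block: standardized features plus a ones column
    Xa = np.empty((B, n, p + 1))
    Xa[:, :, :p] = (X - mean) / scale
    Xa[:, :, p] = 1.0

    # augmented weights: row p of W1a is the hidden bias, row h of W2a the
    # output bias; draws happen in the fixed order W1, b1, W2, b2 per net
    W1a = np.empty((B, p + 1, h))
    W2a = np.empty((B, h + 1, k))
    for i, s in enumerate(init_seeds):
        rng = np.random.default_rng(int(s))
        w1, b1, w2, b2 = _init_weights(rng, p, h, k, config.init_scale)
        W1a[i, :p] = w1
        W1a[i, p] = b1
        W2a[i, :h] = w2
        W2a[i, h] = b2

    lr = config.learning_rate
    lam = config.weight_decay
    Z = np.empty((B, n, h))
    Ha = np.empty((B, n, h + 1))
    Ha[:, :, h] = 1.0
    H = Ha[:, :, :h]
    P = np.empty((B, n, k))
    G = np.empty((B, n, k))
    GH = np.empty((B, n, h))
    tmp = np.empty((B, n, h))
    gW1 = np.empty_like(W1a)
    gW2 = np.empty_like(W2a)
    W2T = np.empty((B, k, h))
    XaT = Xa.transpose(0, 2, 1)
    HaT = Ha.transpose(0, 2, 1)

    for _ in range(config.max_epochs):
        np.matmul(Xa, W1a, out=Z)
        expit(Z, out=Z)
        H[...] = Z
        np.matmul(Ha, W2a, out=P)
        P -= P.max(axis=-1, keepdims=True)
        np.exp(P, out=P)
        P /= P.sum(axis=-1, keepdims=True)
        np.subtract(P, Y, out=G)
        G /= n                                   # mean cross-entropy gradient
        np.matmul(HaT, G, out=gW2)
        gW2[:, :h, :] += (2.0 * lam) * W2a[:, :h, :]
        W2T[...] = W2a[:, :h, :].transpose(0, 2, 1)
        np.matmul(G, W2T, out=GH)
        np.subtract(1.0, Z, out=tmp)
        tmp *= Z
        GH *= tmp                                # logistic derivative
        np.matmul(XaT, GH, out=gW1)
        gW1[:, :p, :] += (2.0 * lam) * W1a[:, :p, :]
        W1a -= lr * gW1
        W2a -= lr * gW2

    return BatchedNets(
        mean_=mean, scale_=scale,
        w1=np.ascontiguousarray(W1a[:, :p, :]),
        b1=np.ascontiguousarray(W1a[:, p:, :]),
        w2=np.ascontiguousarray(W2a[:, :h, :]),
        b2=np.ascontiguousarray(W2a[:, h:, :]),
        classes_=np.asarray(classes),
    )


class SingleLayerNetClassifier:
    """scikit-learn-style estimator around the single-network case.

    Parameters mirror :class:`~adrenomir.config.NNConfig`; fitted attributes
    carry trailing underscores (classes_, mean_, scale_, coefs_). Training is
    deterministic given (X, y, params).
    """

    def __init__(self, hidden_units: int = 3, weight_decay: float = 0.01,
                 max_epochs: int = 200, learning_rate: float = 0.5,
                 init_scale: float = 0.5, seed: int = 0) -> None:
        self.hidden_units = hidden_units
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.init_scale = init_scale
        self.seed = seed

    @classmethod
    def from_config(cls, config: NNConfig) -> "SingleLayerNetClassifier":
        return cls(hidden_units=config.hidden_units,
                   weight_decay=config.weight_decay,
                   max_epochs=config.max_epochs,
                   learning_rate=config.learning_rate,
                   init_scale=config.init_scale, seed=config.seed)

    def _config(self) -> NNConfig:
        return NNConfig(hidden_units=self.hidden_units,
                        weight_decay=self.weight_decay,
                        max_epochs=self.max_epochs,
                        learning_rate=self.learning_rate,
                        init_scale=self.init_scale, seed=self.seed)

    def get_params(self, deep: bool = True) -> dict:
        return {
            "hidden_units": self.hidden_units,
            "weight_decay": self.weight_decay,
            "max_epochs": self.max_epochs,
            "learning_rate": self.learning_rate,
            "init_scale": self.init_scale,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "SingleLayerNetClassifier":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key}")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "SingleLayerNetClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if np.isnan(X).any():
            raise ValueError("X contains masked (NaN) values")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training labels contain a single class")
        Y = (y[:, None] == classes[None, :]).astype(float)
        nets = train_batched(X[None, :, :], Y[None, :, :], classes,
                             self._config(), [self.seed])
        self._nets = nets
        self.classes_ = nets.classes_
        self.mean_ = nets.mean_[0, 0]
        self.scale_ = nets.scale_[0, 0]
        self.coefs_ = (nets.w1[0], nets.b1[0, 0], nets.w2[0], nets.b2[0, 0])
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "classes_"):
            raise ValueError("classifier is not fitted")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self._nets.predict_proba(X[None, :, :])[0]

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=-1)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def train_nn(X, y, config: NNConfig = None) -> SingleLayerNetClassifier:
    """Train a network on the learner set (functional wrapper)."""
    model = (SingleLayerNetClassifier() if config is None
             else SingleLayerNetClassifier.from_config(config))
    return model.fit(X, y)


def predict_nn(model: SingleLayerNetClassifier, x) -> np.ndarray:
    """Class probabilities for one feature vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return model.predict_proba(x[None, :])[0]
    return model.predict_proba(x)
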