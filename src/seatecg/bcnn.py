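"""Binarized 1-D convolutional network for heartbeat-template classification.

A small CNN whose interior weights are binarized to ``alpha * sign(W)``
with a per-filter scaling factor ``alpha = mean|W|``, trained with the
straight-through estimator (gradients pass unchanged through the sign,
clipped where ``|W| > 1``).  Following standard binary-network practice the
first convolution and the final classification layer keep full-precision
weights.  The architecture:

    Conv1D(16, k=7)  -> ReLU -> MaxPool(2)
    Conv1D(32, k=5, binarized) -> ReLU -> MaxPool(2)
    Flatten -> Dense(64, binarized) -> ReLU -> Dense(n_classes) -> softmax

Optimised with Adam on the cross-entropy loss.  The implementation is
plain NumPy (im2col convolutions), sized for heartbeat templates of a few
hundred samples and cohorts of tens of subjects.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["BinarizedConvNet"]


def _binarize(w: np.ndarray) -> np.ndarray:
    """Per-output-filter scaled sign binarization."""
    axes = tuple(range(1, w.ndim))
    alpha = np.mean(np.abs(w), axis=axes, keepdims=True)
    return alpha * np.sign(w + (w == 0))


def _conv1d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid 1-D convolution; x (N,C,L), w (O,C,K) -> (N,O,L-K+1)."""
    patches = sliding_window_view(x, w.shape[2], axis=2)  # (N,C,L',K)
    return np.einsum("nclk,ock->nol", patches, w, optimize=True) + b[None, :, None]


def _conv1d_backward(
    x: np.ndarray, w: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k = w.shape[2]
    patches = sliding_window_view(x, k, axis=2)
    dw = np.einsum("nol,nclk->ock", dy, patches, optimize=True)
    db = dy.sum(axis=(0, 2))
    dy_pad = np.pad(dy, ((0, 0), (0, 0), (k - 1, k - 1)))
    dpatches = sliding_window_view(dy_pad, k, axis=2)  # (N,O,L,K)
    dx = np.einsum("nolk,ock->ncl", dpatches, w[:, :, ::-1], optimize=True)
    return dx, dw, db


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, c, length = x.shape
    trimmed = x[:, :, : (length // 2) * 2].reshape(n, c, length // 2, 2)
    idx = trimmed.argmax(axis=3)
    return trimmed.max(axis=3), idx


def _maxpool2_backward(dy: np.ndarray, idx: np.ndarray, length: int) -> np.ndarray:
    n, c, lp = dy.shape
    dx = np.zeros((n, c, lp, 2))
    np.put_along_axis(dx, idx[..., None], dy[..., None], axis=3)
    dx = dx.reshape(n, c, lp * 2)
    if dx.shape[2] < length:
        dx = np.pad(dx, ((0, 0), (0, 0), (0, length - dx.shape[2])))
    return dx


class BinarizedConvNet:
    """Scikit-learn-style classifier wrapping the binarized CNN.

    Parameters
    ----------
    n_epochs, batch_size, lr : training schedule (Adam).
    random_state : seed for weight initialisation and batch shuffling;
        fixing it makes training bit-for-bit reproducible.
    """

    def __init__(
        self,
        n_epochs: int = 30,
        batch_size: int = 32,
        lr: float = 1e-3,
        random_state: int | None = None,
    ) -> None:
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.lr = lr
        self.random_state = random_state

    # -- parameter handling -------------------------------------------------

    def _init_params(self, input_len: int, n_classes: int,
                     rng: np.random.Generator) -> None:
        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)

        l1 = input_len - 6
        p1 = l1 // 2
        l2 = p1 - 4
        p2 = l2 // 2
        self._flat = 32 * p2
        self.params_ = {
            "w1": he((16, 1, 7), 7),
            "b1": np.zeros(16),
            "w2": he((32, 16, 5), 16 * 5),
            "b2": np.zeros(32),
            "w3": he((64, self._flat), self._flat),
            "b3": np.zeros(64),
            "w4": he((n_classes, 64), 64),
            "b4": np.zeros(n_classes),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params_.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params_.items()}
        self._adam_t = 0

    def _forward(self, x: np.ndarray, train: bool = False):
        p = self.params_
        w2b, w3b = _binarize(p["w2"]), _binarize(p["w3"])
        z1 = _conv1d(x, p["w1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        p1, i1 = _maxpool2(a1)
        z2 = _conv1d(p1, w2b, p["b2"])
        a2 = np.maximum(z2, 0.0)
        p2, i2 = _maxpool2(a2)
        flat = p2.reshape(x.shape[0], -1)
        z3 = flat @ _binarize(p["w3"]).T + p["b3"]
        a3 = np.maximum(z3, 0.0)
        logits = a3 @ p["w4"].T + p["b4"]
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        if not train:
            return probs
        cache = (x, z1, a1, p1, i1, w2b, z2, a2, p2, i2, flat, w3b, z3, a3)
        return probs, cache

    def _backward(self, probs: np.ndarray, y_onehot: np.ndarray, cache) -> dict:
        p = self.params_
        (x, z1, a1, p1, i1, w2b, z2, a2, p2, i2, flat, w3b, z3, a3) = cache
        n = x.shape[0]
        dlogits = (probs - y_onehot) / n
        g = {
            "w4": dlogits.T @ a3,
            "b4": dlogits.sum(axis=0),
        }
        da3 = dlogits @ p["w4"]
        dz3 = da3 * (z3 > 0)
        g["w3"] = dz3.T @ flat          # STE through the binarized dense
        g["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ w3b
        dp2 = dflat.reshape(p2.shape)
        da2 = _maxpool2_backward(dp2, i2, z2.shape[2])
        dz2 = da2 * (z2 > 0)
        dp1, g["w2"], g["b2"] = _conv1d_backward(p1, w2b, dz2)
        da1 = _maxpool2_backward(dp1, i1, z1.shape[2])
        dz1 = da1 * (z1 > 0)
        _, g["w1"], g["b1"] = _conv1d_backward(x, p["w1"], dz1)
        # clipped straight-through estimator for binarized layers
        for k in ("w2", "w3"):
            g[k] = g[k] * (np.abs(p[k]) <= 1.0)
        return g

    def _adam_step(self, grads: dict) -> None:
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, gk in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * gk
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * gk**2
            mhat = self._adam_m[k] / (1 - b1**self._adam_t)
            vhat = self._adam_v[k] / (1 - b2**self._adam_t)
            self.params_[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)

    # -- sklearn-style surface ----------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BinarizedConvNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = self.classes_.size
        if n_classes < 2:
            raise ValueError("need at least two classes")
        rng = np.random.default_rng(self.random_state)
        self._init_params(X.shape[1], n_classes, rng)
        xin = X[:, None, :]
        onehot = np.eye(n_classes)[y_idx]
        n = X.shape[0]
        for _ in range(self.n_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                probs, cache = self._forward(xin[idx], train=True)
                grads = self._backward(probs, onehot[idx], cache)
                self._adam_step(grads)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._forward(X[:, None, :])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_epochs": self.n_epochs,
            "batch_size": self.batch_size,
            "lr": self.lr,
            "random_state": self.random_state,
        }

    def set_params(self, **kw) -> "BinarizedConvNet":
        for k, v in kw.items():
            setattr(self, k, v)
        return self
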