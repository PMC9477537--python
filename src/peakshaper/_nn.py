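"""Minimal deterministic 1-D conv / dense network in numpy.

Small enough to train on a few hundred examples on one CPU in seconds, and
fully reproducible: all initialisation and shuffling flows through a single
``numpy`` Generator.  Only what the shape and combiner models need is
implemented: same-padded 1-D convolution, ReLU, non-overlapping max pooling,
dense layers, a sigmoid head trained with binary cross-entropy and Adam.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1-D convolution: (B, C_in, L) -> (B, C_out, L)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, kernel))
        self.b = np.zeros(c_out)
        self.kernel = kernel
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        pad = self.kernel // 2
        self._xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        win = sliding_window_view(self._xp, self.kernel, axis=2)  # (B,C,L,K)
        self._win = win
        return np.einsum("bclk,ock->bol", win, self.w, optimize=True) + self.b[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        pad = self.kernel // 2
        self.grads[0][...] = np.einsum("bclk,bol->ock", self._win, dy, optimize=True)
        self.grads[1][...] = dy.sum(axis=(0, 2))
        # dx: full correlation of dy with weights
        dyp = np.pad(dy, ((0, 0), (0, 0), (pad, pad)))
        dwin = sliding_window_view(dyp, self.kernel, axis=2)  # (B,O,L,K)
        w_flip = self.w[:, :, ::-1]
        return np.einsum("bolk,ock->bcl", dwin, w_flip, optimize=True)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pool; input length must be divisible by size."""

    def __init__(self, size: int):
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, length = x.shape
        if length % self.size:
            raise ValueError(f"length {length} not divisible by pool size {self.size}")
        xr = x.reshape(b, c, length // self.size, self.size)
        self._argmax = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, lo = dy.shape
        dx = np.zeros((b, c, lo, self.size))
        bi, ci, li = np.indices((b, c, lo))
        dx[bi, ci, li, self._argmax] = dy
        return dx.reshape(self._shape)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w.T


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SequentialNet:
    """A stack of layers ending in a single logit; sigmoid applied on predict."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward_logit(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x[:, 0]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward_logit(x))

    def _backward(self, dlogit: np.ndarray) -> None:
        dy = dlogit[:, None]
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight count mismatch")
        for p, w in zip(params, weights):
            if p.shape != np.asarray(w).shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {np.shape(w)}")
            p[...] = w


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def train_binary(
    net: SequentialNet,
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    *,
    lr: float = 1e-3,
    batch_size: int = 32,
    max_epochs: int = 60,
    patience: int = 8,
    val_fraction: float = 0.2,
) -> dict:
    """Adam + BCE with early stopping on a held-out split; restores best weights.

    Returns a history dict with per-epoch train/validation losses.
    """
    n = x.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    xv, yv = x[val_idx], y[val_idx]
    xt, yt = x[train_idx], y[train_idx]

    opt = Adam(net.parameters(), lr=lr)
    best_loss, best_weights, best_epoch = np.inf, net.get_weights(), -1
    history: dict = {"train_loss": [], "val_loss": []}
    for epoch in range(max_epochs):
        order = rng.permutation(xt.shape[0])
        for lo in range(0, xt.shape[0], batch_size):
            idx = order[lo : lo + batch_size]
            xb, yb = xt[idx], yt[idx]
            p = sigmoid(net.forward_logit(xb))
            net._backward((p - yb) / xb.shape[0])
            opt.step(net.gradients())
        tr = bce_loss(net.predict(xt), yt)
        vl = bce_loss(net.predict(xv), yv)
        history["train_loss"].append(tr)
        history["val_loss"].append(vl)
        if vl < best_loss - 1e-5:
            best_loss, best_weights, best_epoch = vl, net.get_weights(), epoch
        elif epoch - best_epoch >= patience:
            break
    net.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    return history
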