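"""A small, seeded CNN engine on NumPy.

Implements exactly the pieces the acoustic-image classifiers need — valid
(no-padding) 2D convolution via im2col/GEMM, 2x2 max-pooling, dense layers,
ReLU, a sigmoid output trained with binary cross-entropy on logits, and
Adam — with fully deterministic initialization and shuffling from a seed.
Data layout is channels-last: ``(batch, height, width, channels)``,
float32 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "ReLU", "MaxPool2x2", "Flatten", "Dense", "Sequential", "Adam",
           "sigmoid", "bce_with_logits"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    z = z.ravel()
    y = y.ravel().astype(np.float64)
    # softplus(z) - y*z, computed stably
    loss = float(np.mean(np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - y) / z.size).astype(np.float32)
    return loss, grad


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2D(Layer):
    """Valid 2D convolution, stride 1, channels-last, He-initialized."""

    def __init__(self, kh: int, kw: int, c_in: int, c_out: int, rng: np.random.Generator,
                 first_layer: bool = False):
        self.kh, self.kw, self.c_in, self.c_out = kh, kw, c_in, c_out
        fan_in = kh * kw * c_in
        self.w = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.first_layer = first_layer  # skip input gradient at the bottom of the net

    def output_shape(self, h: int, w: int) -> tuple[int, int]:
        if h < self.kh or w < self.kw:
            raise ValueError(f"kernel {self.kh}x{self.kw} larger than input {h}x{w}")
        return h - self.kh + 1, w - self.kw + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        oh, ow = self.output_shape(h, w)
        cols = sliding_window_view(x, (self.kh, self.kw), axis=(1, 2))  # (n, oh, ow, c, kh, kw)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * oh * ow, self.kh * self.kw * c)
        self._cols, self._xshape = cols, x.shape
        return (cols @ self.w + self.b).reshape(n, oh, ow, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        n, oh, ow, _ = dout.shape
        dflat = dout.reshape(n * oh * ow, self.c_out)
        self.dw = self._cols.T @ dflat
        self.db = dflat.sum(axis=0)
        if self.first_layer:
            return None
        dcols = (dflat @ self.w.T).reshape(n, oh, ow, self.kh, self.kw, self.c_in)
        dx = np.zeros(self._xshape, dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, i:i + oh, j:j + ow, :] += dcols[:, :, :, i, j, :]
        return dx

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(np.float32)


class MaxPool2x2(Layer):
    """2x2 max pool with stride 2; trailing odd rows/columns are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._xshape = x.shape
        xc = x[:, :2 * h2, :2 * w2, :]
        win = xc.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h2, w2, 4, c)
        self._idx = win.argmax(axis=3)
        return np.take_along_axis(win, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h2, w2, c = dout.shape
        dwin = np.zeros((n, h2, w2, 4, c), dtype=np.float32)
        np.put_along_axis(dwin, self._idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = np.zeros(self._xshape, dtype=np.float32)
        dx[:, :2 * h2, :2 * w2, :] = (
            dwin.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h2, 2 * w2, c)
        )
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return (dout @ self.w.T).astype(np.float32)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: list[np.ndarray] = []
        self.v: list[np.ndarray] = []

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self.m:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


_CACHE_ATTRS = ("_cols", "_xshape", "_mask", "_idx", "_x")


@dataclass
class Sequential:
    """A feed-forward stack with a single sigmoid/BCE output head."""

    layers: list = field(default_factory=list)

    def clear_caches(self) -> None:
        """Drop forward-pass activations kept for backprop (saves memory and
        keeps serialized models small)."""
        for layer in self.layers:
            for attr in _CACHE_ATTRS:
                if hasattr(layer, attr):
                    delattr(layer, attr)

    def __getstate__(self):
        self.clear_caches()
        return self.__dict__

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
            if dout is None:
                break

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def predict_logits(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for lo in range(0, x.shape[0], batch_size):
            out.append(self.forward(x[lo:lo + batch_size]).ravel())
        return np.concatenate(out) if out else np.empty(0, dtype=np.float32)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return sigmoid(self.predict_logits(x, batch_size))

    def state_dict(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p[...] = s


def train_loop(
    model: Sequential,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    epochs: int,
    batch_size: int,
    learning_rate: float,
    seed: int,
    patience: int | None = 3,
) -> dict[str, list[float]]:
    """Mini-batch Adam training; returns the per-epoch history and leaves the
    model at its best-validation-accuracy checkpoint.

    Early-stops when validation loss has not improved for ``patience``
    epochs.  Raises on a non-finite loss.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(lr=learning_rate)
    history: dict[str, list[float]] = {k: [] for k in
                                       ("train_loss", "train_acc", "val_loss", "val_acc")}
    best_state = model.state_dict()
    best_val_acc = -np.inf
    best_val_loss = np.inf
    stall = 0
    n = x_train.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        correct = 0
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            xb, yb = x_train[idx], y_train[idx]
            z = model.forward(xb).ravel()
            loss, dz = bce_with_logits(z, yb)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}: {loss}")
            losses.append(loss * len(idx))
            correct += int(((z >= 0) == (yb > 0.5)).sum())
            model.backward(dz.reshape(-1, 1))
            opt.step(model.params(), model.grads())
        zv = model.predict_logits(x_val)
        val_loss, _ = bce_with_logits(zv, y_val)
        val_acc = float(np.mean((zv >= 0) == (y_val > 0.5)))
        history["train_loss"].append(sum(losses) / n)
        history["train_acc"].append(correct / n)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_acc > best_val_acc:
            best_val_acc = val_acc
            best_state = model.state_dict()
        if val_loss < best_val_loss - 1e-6:
            best_val_loss = val_loss
            stall = 0
        else:
            stall += 1
            if patience is not None and stall > patience:
                break
    model.load_state_dict(best_state)
    model.clear_caches()
    return history
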