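"""Small 1-D convolutional network engine on NumPy.

Implements exactly the layer set the two classifiers need — 1-D
convolution ("same" padding, arbitrary stride), ReLU, max/average pooling,
global average pooling, flatten, dense, residual blocks with optional 1x1
projection skips, and a parallel branch-concat container — with explicit
forward/backward passes and an Adam optimizer.  Data layout is
(batch, channels, length).

Kept deliberately minimal: no autograd, no GPU, deterministic under a
fixed seed, which is all the pipeline requires.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def out_length(length: int, stride: int) -> int:
    """Output length of a same-padded convolution."""
    return (length - 1) // stride + 1


class Conv1D(Layer):
    """Same-padded 1-D convolution, odd kernel, arbitrary stride."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 *, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        std = math.sqrt(2.0 / (in_ch * kernel))
        self.W = Param(rng.normal(0.0, std, size=(out_ch, in_ch * kernel)))
        self.b = Param(np.zeros(out_ch))
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, L = x.shape
        k, s = self.kernel, self.stride
        pl = (k - 1) // 2
        pr = k - 1 - pl
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        win = sliding_window_view(xp, k, axis=2)[:, :, ::s, :]  # (B, C, Lout, k)
        Lout = win.shape[2]
        cols = win.transpose(0, 2, 1, 3).reshape(B, Lout, C * k)
        out = cols @ self.W.value.T + self.b.value  # (B, Lout, out_ch)
        if train:
            self._cache = (cols, (B, C, L, pl, pr, Lout))
        return out.transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, (B, C, L, pl, pr, Lout) = self._cache
        k, s = self.kernel, self.stride
        gt = grad.transpose(0, 2, 1)  # (B, Lout, out_ch)
        self.W.grad += np.einsum("blo,blm->om", gt, cols)
        self.b.grad += gt.sum(axis=(0, 1))
        dcols = (gt @ self.W.value).reshape(B, Lout, C, k).transpose(0, 2, 1, 3)
        dxp = np.zeros((B, C, L + pl + pr))
        for j in range(k):
            dxp[:, :, j : j + s * Lout : s] += dcols[:, :, :, j]
        return dxp[:, :, pl : pl + L]

    def params(self) -> list[Param]:
        return [self.W, self.b]


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder shorter than the
    window is dropped (floor semantics)."""

    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x, train=False):
        B, C, L = x.shape
        n = L // self.pool
        if n == 0:
            raise ValueError(f"input length {L} shorter than pool size {self.pool}")
        xc = x[:, :, : n * self.pool].reshape(B, C, n, self.pool)
        idx = xc.argmax(axis=3)
        if train:
            self._cache = (idx, (B, C, L, n))
        return np.take_along_axis(xc, idx[..., None], axis=3)[..., 0]

    def backward(self, grad):
        idx, (B, C, L, n) = self._cache
        g4 = np.zeros((B, C, n, self.pool))
        np.put_along_axis(g4, idx[..., None], grad[..., None], axis=3)
        dx = np.zeros((B, C, L))
        dx[:, :, : n * self.pool] = g4.reshape(B, C, n * self.pool)
        return dx


class AvgPool1D(Layer):
    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x, train=False):
        B, C, L = x.shape
        n = L // self.pool
        if n == 0:
            raise ValueError(f"input length {L} shorter than pool size {self.pool}")
        if train:
            self._shape = (B, C, L, n)
        return x[:, :, : n * self.pool].reshape(B, C, n, self.pool).mean(axis=3)

    def backward(self, grad):
        B, C, L, n = self._shape
        dx = np.zeros((B, C, L))
        dx[:, :, : n * self.pool] = np.repeat(grad / self.pool, self.pool, axis=2)
        return dx


class GlobalAvgPool(Layer):
    """Per-channel mean over the length axis: (B, C, L) -> (B, C)."""

    def forward(self, x, train=False):
        if train:
            self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._L, axis=2) / self._L


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, *, rng: np.random.Generator):
        std = math.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, std, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T

    def params(self):
        return [self.W, self.b]


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class BranchConcat(Layer):
    """Run branches on the same input, concatenate their (B, d_i) outputs."""

    def __init__(self, branches: Sequence[Layer]):
        self.branches = list(branches)

    def forward(self, x, train=False):
        outs = [b.forward(x, train) for b in self.branches]
        self._widths = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, grad):
        dx = None
        start = 0
        for b, w in zip(self.branches, self._widths):
            g = grad[:, start : start + w]
            start += w
            d = b.backward(g)
            dx = d if dx is None else dx + d
        return dx

    def params(self):
        return [p for b in self.branches for p in b.params()]


class ResidualBlock(Layer):
    """conv(-relu-conv)* + skip, with an optional 1x1 projection on the skip
    path whenever channel count or stride changes shape; final ReLU after
    the add."""

    def __init__(self, convs: Sequence[Conv1D], projection: Conv1D | None):
        self.convs = list(convs)
        self.relus = [ReLU() for _ in range(len(self.convs) - 1)]
        self.projection = projection
        self.out_relu = ReLU()

    def forward(self, x, train=False):
        h = x
        for i, conv in enumerate(self.convs):
            h = conv.forward(h, train)
            if i < len(self.convs) - 1:
                h = self.relus[i].forward(h, train)
        skip = self.projection.forward(x, train) if self.projection is not None else x
        return self.out_relu.forward(h + skip, train)

    def backward(self, grad):
        g = self.out_relu.backward(grad)
        dskip = self.projection.backward(g) if self.projection is not None else g
        h = g
        for i in range(len(self.convs) - 1, -1, -1):
            if i < len(self.convs) - 1:
                h = self.relus[i].backward(h)
            h = self.convs[i].backward(h)
        return h + dskip

    def params(self):
        ps = [p for c in self.convs for p in c.params()]
        if self.projection is not None:
            ps.extend(self.projection.params())
        return ps


class Adam:
    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def bce_loss_and_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on raw logits (B, 1); returns (loss, dlogits)."""
    p = sigmoid(logits[:, 0])
    eps = 1e-12
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    dlogits = ((p - y) / len(y))[:, None]
    return float(loss), dlogits

def cce_loss_and_grad(logits: np.ndarray, Y: np.ndarray) -> tuple[float, np.ndarray]:
    """Categorical cross-entropy on raw logits (B, K) with one-hot Y."""
    p = softmax(logits)
    eps = 1e-12
    loss = -np.mean(np.sum(Y * np.log(p + eps), axis=1))
    dlogits = (p - Y) / len(Y)
    return float(loss), dlogits


def get_state(net: Layer) -> list[np.ndarray]:
    return [p.value.copy() for p in net.params()]


def set_state(net: Layer, state: Sequence[np.ndarray]) -> None:
    for p, s in zip(net.params(), state):
        p.value[...] = s


def train_network(
    net: Layer,
    X: np.ndarray,
    Y: np.ndarray,
    *,
    loss: str,
    lr: float,
    batch_size: int,
    epochs: int,
    seed: int,
    X_val: np.ndarray | None = None,
    Y_val: np.ndarray | None = None,
    patience: int | None = None,
) -> dict:
    """Mini-batch Adam training; returns a history dict.

    ``loss`` is "bce" (Y is a 0/1 vector) or "cce" (Y is one-hot rows).
    With validation data and ``patience`` set, stops early on stagnating
    validation loss and restores the best parameter state.
    """
    loss_fn = {"bce": bce_loss_and_grad, "cce": cce_loss_and_grad}[loss]
    rng = np.random.default_rng(seed)
    opt = Adam(net.params(), lr=lr)
    n = X.shape[0]
    history: dict = {"loss": [], "val_loss": []}
    best_val = np.inf
    best_state = None
    bad_epochs = 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits = net.forward(X[idx], train=True)
            if not np.isfinite(logits).all():
                raise RuntimeError(
                    f"non-finite activations at epoch {epoch}, batch {start // batch_size}"
                )
            batch_loss, dlogits = loss_fn(logits, Y[idx])
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {start // batch_size}"
                )
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            total += batch_loss * len(idx)
        history["loss"].append(total / n)
        if X_val is not None and len(X_val):
            val_logits = net.forward(X_val, train=False)
            val_loss, _ = loss_fn(val_logits, Y_val)
            history["val_loss"].append(val_loss)
            if patience is not None:
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_state = get_state(net)
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                    if bad_epochs > patience:
                        break
    if best_state is not None:
        set_state(net, best_state)
    return history
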