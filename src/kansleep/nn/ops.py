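"""Minimal NumPy neural-network primitives with analytic gradients.

Everything here is deliberately CPU-only, float32, and deterministic under a
caller-supplied ``numpy.random.Generator``.  Layers follow the usual
forward/backward contract: ``forward`` caches what ``backward`` needs;
``backward`` returns the gradient w.r.t. the input and accumulates parameter
gradients on the layer.

Conventions (stated once, used by the whole package):

- 1-D convolutions use the "same" zero-padded convention: output length is
  ``ceil(L / stride)``, with total padding ``max((out-1)*stride + k - L, 0)``
  split left-biased (``pad_left = total // 2``).
- Max pools use the valid, non-overlapping convention: output length is
  ``floor((L - k) / stride) + 1``.
"""

from __future__ import annotations

import math

import numpy as np


def conv_same_out_len(length: int, stride: int) -> int:
    return -(-length // stride)  # ceil


def pool_out_len(length: int, k: int, stride: int) -> int:
    return (length - k) // stride + 1


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """``x``: (B, C, L) already padded -> (B, out, C*k) patch matrix."""
    b, c, l = x.shape
    out = (l - k) // stride + 1
    s0, s1, s2 = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(b, c, out, k), strides=(s0, s1, s2 * stride, s2), writeable=False
    )
    return np.ascontiguousarray(patches.transpose(0, 2, 1, 3)).reshape(b, out, c * k)


class Conv1d:
    """Same-padded strided 1-D convolution, (B, C_in, L) -> (B, C_out, out)."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int,
                 rng: np.random.Generator):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        scale = math.sqrt(2.0 / (c_in * k))  # He init for the rectifier
        self.w = (rng.standard_normal((c_out, c_in, k)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    def out_len(self, length: int) -> int:
        return conv_same_out_len(length, self.stride)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, c, l = x.shape
        out = self.out_len(l)
        pad_total = max((out - 1) * self.stride + self.k - l, 0)
        pl = pad_total // 2
        pr = pad_total - pl
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr))).astype(np.float32, copy=False)
        cols = _im2col(xp, self.k, self.stride)  # (B, out, C*k)
        wmat = self.w.reshape(self.c_out, -1)
        y = cols @ wmat.T + self.b  # (B, out, C_out)
        self._cache = (cols, xp.shape, pl, l)
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, pl, l = self._cache
        b, _, out = dy.shape
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 1))  # (B, out, C_out)
        wmat = self.w.reshape(self.c_out, -1)
        self.gw += (dyt.reshape(-1, self.c_out).T @ cols.reshape(-1, cols.shape[2])
                    ).reshape(self.w.shape)
        self.gb += dyt.sum(axis=(0, 1))
        dcols = dyt @ wmat  # (B, out, C*k)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        dpatch = dcols.reshape(b, out, self.c_in, self.k)
        for j in range(self.k):  # scatter-add per kernel offset
            idx = np.arange(out) * self.stride + j
            np.add.at(dxp, (slice(None), slice(None), idx),
                      dpatch[:, :, :, j].transpose(0, 2, 1))
        return dxp[:, :, pl:pl + l]


class MaxPool1d:
    """Valid non-overlapping max pool (k == stride in all default specs)."""

    def __init__(self, k: int, stride: int):
        self.k, self.stride = k, stride
        self._cache = None

    def params(self):
        return []

    def out_len(self, length: int) -> int:
        return pool_out_len(length, self.k, self.stride)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, c, l = x.shape
        out = self.out_len(l)
        s0, s1, s2 = x.strides
        win = np.lib.stride_tricks.as_strided(
            x, shape=(b, c, out, self.k),
            strides=(s0, s1, s2 * self.stride, s2), writeable=False)
        arg = win.argmax(axis=3)
        y = np.take_along_axis(win, arg[..., None], axis=3)[..., 0]
        self._cache = (arg, l)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        arg, l = self._cache
        b, c, out = dy.shape
        dx = np.zeros((b, c, l), dtype=np.float32)
        pos = np.arange(out) * self.stride + arg  # (B, C, out)
        bi = np.arange(b)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(dx, (bi, ci, pos), dy)
        return dx


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def out_len(self, length: int) -> int:
        return length

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout:
    """Inverted dropout; identity when not training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def params(self):
        return []

    def out_len(self, length: int) -> int:
        return length

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_out, n_in)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.gw += dy.T @ self._x
        self.gb += dy.sum(axis=0)
        return dy @ self.w


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits.

    ``targets`` are integer class codes; gradient is ``(p - onehot)/B``.
    """
    p = softmax(logits)
    n = logits.shape[0]
    ll = -np.log(np.maximum(p[np.arange(n), targets], 1e-12))
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return float(ll.mean()), (grad / n).astype(np.float32)


class Adam:
    """Adaptive-moment optimizer over a flat list of (param, grad) pairs."""

    def __init__(self, param_grads, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = list(param_grads)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.pairs:
            g[...] = 0.0
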