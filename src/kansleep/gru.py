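"""Gated recurrent unit and the final stage classifier head.

The cell follows the standard two-gate formulation: a reset gate decides how
much of the previous hidden state enters the tanh candidate, an update gate
interpolates between the previous state and the candidate,

    r_t = sigmoid(W_xr x_t + W_hr h_{t-1} + b_r)
    z_t = sigmoid(W_xz x_t + W_hz h_{t-1} + b_z)
    h~_t = tanh(W_xh x_t + W_hh (r_t * h_{t-1}) + b_h)
    h_t = (1 - z_t) * h_{t-1} + z_t * h~_t

so each new state is a componentwise convex combination of the old state and
the candidate.  Default sizes are input 64 (the KAN output width) and hidden
32.  The classifier head is a single affine map from the hidden state to the
five stage scores, softmax-normalized.

Forward passes are vectorized over a batch of sequences; the backward pass
is standard truncated-free BPTT with analytic gradients.
"""

from __future__ import annotations

import numpy as np

from .nn.ops import softmax
from .stages import N_STAGES


def _sigmoid(x):
    # piecewise form avoids overflow for large |x|
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class GRUParams:
    """Gate weights/biases of a single GRU cell (input ``nx`` -> hidden ``nh``)."""

    def __init__(self, nx: int = 64, nh: int = 32,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.nx, self.nh = nx, nh
        sx, sh = 1.0 / np.sqrt(nx), 1.0 / np.sqrt(nh)

        def mk(shape, s):
            return rng.uniform(-s, s, size=shape)

        self.w_xr, self.w_hr, self.b_r = mk((nh, nx), sx), mk((nh, nh), sh), np.zeros(nh)
        self.w_xz, self.w_hz, self.b_z = mk((nh, nx), sx), mk((nh, nh), sh), np.zeros(nh)
        self.w_xh, self.w_hh, self.b_h = mk((nh, nx), sx), mk((nh, nh), sh), np.zeros(nh)
        self._names = ["w_xr", "w_hr", "b_r", "w_xz", "w_hz", "b_z",
                       "w_xh", "w_hh", "b_h"]
        self.grads = {n: np.zeros_like(getattr(self, n)) for n in self._names}

    def params(self):
        return [(n, getattr(self, n), self.grads[n]) for n in self._names]

    def zero_grad(self):
        for g in self.grads.values():
            g[...] = 0.0


def gru_step(x, h_prev, p: GRUParams):
    """One cell update; returns ``(h_new, r, z, h_candidate)``.

    ``x``: (B, nx) or (nx,); ``h_prev``: (B, nh) or (nh,).
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=np.float64))
    if x.shape[1] != p.nx or h_prev.shape[1] != p.nh:
        raise ValueError("input/hidden width mismatch with GRU parameters")
    r = _sigmoid(x @ p.w_xr.T + h_prev @ p.w_hr.T + p.b_r)
    z = _sigmoid(x @ p.w_xz.T + h_prev @ p.w_hz.T + p.b_z)
    h_cand = np.tanh(x @ p.w_xh.T + (r * h_prev) @ p.w_hh.T + p.b_h)
    h_new = (1.0 - z) * h_prev + z * h_cand
    return h_new, r, z, h_cand


def gru_sequence(xs, p: GRUParams, h0=None):
    """Left-to-right recurrence over ``xs``: (B, T, nx) or (T, nx).

    Returns the hidden sequence with matching leading shape; ``h0`` defaults
    to zeros.
    """
    xs = np.asarray(xs, dtype=np.float64)
    squeeze = xs.ndim == 2
    if squeeze:
        xs = xs[None]
    if xs.shape[1] < 1:
        raise ValueError("empty sequence")
    b, t, _ = xs.shape
    h = np.zeros((b, p.nh)) if h0 is None else np.atleast_2d(np.asarray(h0, float))
    hs = np.empty((b, t, p.nh))
    for i in range(t):
        h, _, _, _ = gru_step(xs[:, i], h, p)
        hs[:, i] = h
    return hs[0] if squeeze else hs


class GRUSequence:
    """Trainable GRU over batches of sequences, with BPTT backward."""

    def __init__(self, p: GRUParams):
        self.p = p
        self._cache = None

    def params(self):
        return self.p.params()

    def forward(self, xs: np.ndarray, training: bool = False) -> np.ndarray:
        xs = np.asarray(xs, dtype=np.float64)
        b, t, _ = xs.shape
        p = self.p
        h = np.zeros((b, p.nh))
        hs = np.empty((b, t, p.nh))
        cache = []
        for i in range(t):
            h_prev = h
            h, r, z, hc = gru_step(xs[:, i], h_prev, p)
            hs[:, i] = h
            cache.append((xs[:, i], h_prev, r, z, hc))
        self._cache = cache
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        p = self.p
        g = p.grads
        cache = self._cache
        b, t, _ = dhs.shape
        dxs = np.empty((b, t, p.nx))
        dh_next = np.zeros((b, p.nh))
        for i in range(t - 1, -1, -1):
            x, h_prev, r, z, hc = cache[i]
            dh = dhs[:, i] + dh_next
            dz = dh * (hc - h_prev) * z * (1.0 - z)
            dhc = dh * z * (1.0 - hc ** 2)
            dr = (dhc @ p.w_hh) * h_prev * r * (1.0 - r)
            g["w_xz"] += dz.T @ x
            g["w_hz"] += dz.T @ h_prev
            g["b_z"] += dz.sum(0)
            g["w_xh"] += dhc.T @ x
            g["w_hh"] += dhc.T @ (r * h_prev)
            g["b_h"] += dhc.sum(0)
            g["w_xr"] += dr.T @ x
            g["w_hr"] += dr.T @ h_prev
            g["b_r"] += dr.sum(0)
            dxs[:, i] = dz @ p.w_xz + dhc @ p.w_xh + dr @ p.w_xr
            dh_next = (dh * (1.0 - z) + (dhc @ p.w_hh) * r
                       + dz @ p.w_hz + dr @ p.w_hr)
        return dxs


class HeadParams:
    """Affine map hidden -> 5 stage scores, softmax-normalized."""

    def __init__(self, nh: int = 32, n_classes: int = N_STAGES,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = rng.uniform(-1, 1, size=(n_classes, nh)) / np.sqrt(nh)
        self.b = np.zeros(n_classes)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        flat_x = self._x.reshape(-1, self._x.shape[-1])
        flat_dy = dy.reshape(-1, dy.shape[-1])
        self.gw += flat_dy.T @ flat_x
        self.gb += flat_dy.sum(0)
        return dy @ self.w

    def zero_grad(self):
        self.gw[...] = 0.0
        self.gb[...] = 0.0


def classify_sequence(features, gru: GRUParams, head: HeadParams) -> np.ndarray:
    """Per-step stage probabilities for a sequence of fused feature vectors.

    ``features``: (T, 64) or (B, T, 64) -> probabilities (..., T, 5), each
    step summing to one; the argmax defines the predicted stage.
    """
    hs = gru_sequence(features, gru)
    return softmax(head.forward(hs))
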