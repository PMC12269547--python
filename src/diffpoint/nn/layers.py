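"""NumPy neural-network layers with hand-derived gradients.

Every layer caches what its backward pass needs during ``forward`` and
returns the gradient with respect to its input from ``backward``.
Parameters are :class:`Param` objects (value + accumulated gradient).

Padded frames sit at the tail of each sequence in both time directions:
the backward-direction LSTM consumes sequences reversed *within their
true length*, so padding never leaks into real frames and batched
inference matches single-trajectory inference exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = ["Param", "LSTMDirection", "BiLSTMLayer", "LayerNorm", "Linear", "reverse_padded"]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


def reverse_padded(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence within its true length; padding stays in place.

    Involution: applying it twice restores the input, so it is its own
    gradient operation.
    """
    B, T = x.shape[0], x.shape[1]
    t = np.arange(T)[None, :]
    idx = np.where(t < lengths[:, None], lengths[:, None] - 1 - t, t)
    return x[np.arange(B)[:, None], idx]


class LSTMDirection:
    """Single-direction LSTM over (B, T, in_dim) -> (B, T, hidden).

    Gate order (i, f, g, o) with two bias vectors per layer, matching the
    common per-layer parameter count 4h(in + h) + 8h.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(hidden)
        self.in_dim, self.hidden = in_dim, hidden
        self.W_ih = Param(rng.uniform(-k, k, (4 * hidden, in_dim)))
        self.W_hh = Param(rng.uniform(-k, k, (4 * hidden, hidden)))
        self.b_ih = Param(rng.uniform(-k, k, 4 * hidden))
        self.b_hh = Param(rng.uniform(-k, k, 4 * hidden))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W_ih, self.W_hh, self.b_ih, self.b_hh]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        h = self.hidden
        pre = x @ self.W_ih.value.T + (self.b_ih.value + self.b_hh.value)
        H = np.zeros((B, T, h))
        I = np.empty((B, T, h))
        F = np.empty((B, T, h))
        G = np.empty((B, T, h))
        O = np.empty((B, T, h))
        C = np.empty((B, T, h))
        TC = np.empty((B, T, h))
        h_t = np.zeros((B, h))
        c_t = np.zeros((B, h))
        Whh_T = self.W_hh.value.T
        for t in range(T):
            z = pre[:, t] + h_t @ Whh_T
            sig = _sigmoid(np.concatenate([z[:, : 2 * h], z[:, 3 * h :]], axis=1))
            i, f, o = sig[:, :h], sig[:, h : 2 * h], sig[:, 2 * h :]
            g = np.tanh(z[:, 2 * h : 3 * h])
            c_t = f * c_t + i * g
            tc = np.tanh(c_t)
            h_t = o * tc
            I[:, t], F[:, t], G[:, t], O[:, t] = i, f, g, o
            C[:, t], TC[:, t], H[:, t] = c_t, tc, h_t
        self._cache = (x, H, I, F, G, O, C, TC)
        return H

    def backward(self, dH: np.ndarray) -> np.ndarray:
        x, H, I, F, G, O, C, TC = self._cache
        B, T, _ = x.shape
        h = self.hidden
        dZ = np.zeros((B, T, 4 * h))
        dh_next = np.zeros((B, h))
        dc_next = np.zeros((B, h))
        Whh = self.W_hh.value
        for t in range(T - 1, -1, -1):
            dh = dH[:, t] + dh_next
            i, f, g, o = I[:, t], F[:, t], G[:, t], O[:, t]
            tc = TC[:, t]
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            c_prev = C[:, t - 1] if t > 0 else 0.0
            dz = np.empty((B, 4 * h))
            dz[:, :h] = dc * g * i * (1.0 - i)
            dz[:, h : 2 * h] = dc * c_prev * f * (1.0 - f)
            dz[:, 2 * h : 3 * h] = dc * i * (1.0 - g * g)
            dz[:, 3 * h :] = do * o * (1.0 - o)
            dc_next = dc * f
            dh_next = dz @ Whh
            dZ[:, t] = dz
        h_prev = np.concatenate([np.zeros((B, 1, h)), H[:, :-1]], axis=1)
        self.W_ih.grad += np.einsum("btk,bti->ki", dZ, x)
        self.W_hh.grad += np.einsum("btk,bth->kh", dZ, h_prev)
        db = dZ.sum(axis=(0, 1))
        self.b_ih.grad += db
        self.b_hh.grad += db
        return dZ @ self.W_ih.value


class BiLSTMLayer:
    """Bidirectional LSTM: forward + length-reversed passes, concatenated."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.fwd = LSTMDirection(in_dim, hidden, rng)
        self.bwd = LSTMDirection(in_dim, hidden, rng)
        self.hidden = hidden
        self._lengths = None

    def params(self) -> list[Param]:
        return self.fwd.params() + self.bwd.params()

    def forward(self, x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        self._lengths = lengths
        hf = self.fwd.forward(x)
        hb = reverse_padded(self.bwd.forward(reverse_padded(x, lengths)), lengths)
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h = self.hidden
        dxf = self.fwd.backward(dout[:, :, :h])
        dxb_rev = self.bwd.backward(reverse_padded(dout[:, :, h:], self._lengths))
        return dxf + reverse_padded(dxb_rev, self._lengths)


class LayerNorm:
    """Per-frame layer normalisation over the feature axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Param(np.ones(dim))
        self.bias = Param(np.zeros(dim))
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gain, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gain.value * xhat + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gain.grad += (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
        self.bias.grad += dy.sum(axis=tuple(range(dy.ndim - 1)))
        dxhat = dy * self.gain.value
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class Linear:
    """Affine map on the trailing axis."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(in_dim)
        self.W = Param(rng.uniform(-k, k, (out_dim, in_dim)))
        self.b = Param(rng.uniform(-k, k, out_dim))
        self._x = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        dy2 = dy.reshape(-1, dy.shape[-1])
        x2 = x.reshape(-1, x.shape[-1])
        self.W.grad += dy2.T @ x2
        self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.value
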