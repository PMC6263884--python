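"""A small, deterministic NumPy neural-network core.

Implements exactly the layers the cycle classifier needs -- 1-D convolution
(valid padding, time axis), ReLU, max-pooling, stacked LSTMs with inverted
dropout, a dense softmax head -- together with categorical cross-entropy and
an Adam optimizer.  Everything runs in float32 through BLAS matmuls; all
randomness (initialization, shuffling, dropout masks) is drawn from a single
``numpy.random.Generator``, so training is bit-reproducible for a fixed seed
on a given platform.

Array layout is ``(batch, time, channels)`` throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D", "ReLU", "MaxPool1D", "LSTM", "Dropout", "Dense",
    "Sequential", "Adam", "softmax", "softmax_cross_entropy",
]

_F = np.float32


def _glorot(rng: np.random.Generator, shape, dtype=_F) -> np.ndarray:
    fan_in, fan_out = shape[0] if len(shape) == 2 else int(np.prod(shape[:-1])), shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal(rng: np.random.Generator, n: int, m: int, dtype=_F) -> np.ndarray:
    a = rng.standard_normal((max(n, m), min(n, m)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    q = q if n >= m else q.T
    return q[:n, :m].astype(dtype)


class Layer:
    """Base layer: subclasses define forward/backward and expose params."""

    def params(self):
        return []

    def forward(self, x, train):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1D(Layer):
    """Valid 1-D convolution over the time axis, all channels fused.

    Input (B, L, C_in) -> output (B, L - k + 1, filters).  Implemented as an
    im2col sliding-window view followed by one matmul.
    """

    def __init__(self, c_in: int, filters: int, kernel: int, rng: np.random.Generator,
                 dtype=_F):
        self.kernel = kernel
        self.W = _glorot(rng, (kernel * c_in, filters), dtype)
        self.b = np.zeros(filters, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=False):
        B, L, C = x.shape
        k = self.kernel
        if L < k:
            raise ValueError(f"input length {L} shorter than kernel {k}")
        # (B, L-k+1, k, C) view -> (B, L-k+1, k*C)
        patches = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (B, L-k+1, C, k)
        patches = np.ascontiguousarray(patches.transpose(0, 1, 3, 2)).reshape(B, L - k + 1, k * C)
        self._patches, self._in_shape = patches, x.shape
        return patches @ self.W + self.b

    def backward(self, dout):
        B, Lo, F = dout.shape
        k = self.kernel
        _, L, C = self._in_shape
        flat = dout.reshape(-1, F)
        self.dW[...] = self._patches.reshape(-1, k * C).T @ flat
        self.db[...] = flat.sum(axis=0)
        dpatches = (dout @ self.W.T).reshape(B, Lo, k, C)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        for i in range(k):
            dx[:, i:i + Lo, :] += dpatches[:, :, i, :]
        return dx


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0)


class MaxPool1D(Layer):
    """Non-overlapping max pooling over time; trailing remainder is dropped."""

    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x, train=False):
        B, L, C = x.shape
        Lo = L // self.pool
        x = x[:, :Lo * self.pool, :].reshape(B, Lo, self.pool, C)
        self._argmax = x.argmax(axis=2)
        self._in_shape = (B, L, C)
        return x.max(axis=2)

    def backward(self, dout):
        B, Lo, C = dout.shape
        dx = np.zeros((B, Lo, self.pool, C), dtype=dout.dtype)
        b, t, c = np.ogrid[:B, :Lo, :C]
        dx[b, t, self._argmax, c] = dout
        dx = dx.reshape(B, Lo * self.pool, C)
        full = np.zeros(self._in_shape, dtype=dout.dtype)
        full[:, :Lo * self.pool, :] = dx
        return full


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class LSTM(Layer):
    """Single LSTM layer with full backpropagation through time.

    Gate order in the packed weight matrices is (input, forget, cell, output).
    Input weights are Glorot-uniform, recurrent weights orthogonal, biases
    zero except the forget gate at +1.  ``return_sequences`` controls whether
    the full hidden sequence (for stacking) or only the last hidden state
    (for the classifier head) is emitted.
    """

    def __init__(self, c_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = True, dtype=_F):
        H = self.units = units
        self.return_sequences = return_sequences
        self.Wx = _glorot(rng, (c_in, 4 * H), dtype)
        self.Wh = np.concatenate([_orthogonal(rng, H, H, dtype) for _ in range(4)], axis=1)
        self.b = np.zeros(4 * H, dtype=dtype)
        self.b[H:2 * H] = 1.0  # forget-gate bias
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.Wx, self.dWx), (self.Wh, self.dWh), (self.b, self.db)]

    def forward(self, x, train=False):
        B, T, C = x.shape
        H = self.units
        pre = (x.reshape(-1, C) @ self.Wx).reshape(B, T, 4 * H)
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        gates = np.empty((B, T, 4 * H), dtype=x.dtype)
        hs = np.empty((B, T, H), dtype=x.dtype)
        cs = np.empty((B, T, H), dtype=x.dtype)
        for t in range(T):
            z = pre[:, t] + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[:, t, :H], gates[:, t, H:2 * H] = i, f
            gates[:, t, 2 * H:3 * H], gates[:, t, 3 * H:] = g, o
            cs[:, t], hs[:, t] = c, h
        self._x, self._gates, self._hs, self._cs = x, gates, hs, cs
        return hs if self.return_sequences else hs[:, -1]

    def backward(self, dout):
        x, gates, hs, cs = self._x, self._gates, self._hs, self._cs
        B, T, C = x.shape
        H = self.units
        if self.return_sequences:
            dh_seq = dout
        else:
            dh_seq = np.zeros((B, T, H), dtype=dout.dtype)
            dh_seq[:, -1] = dout
        dz_all = np.empty((B, T, 4 * H), dtype=dout.dtype)
        dh_next = np.zeros((B, H), dtype=dout.dtype)
        dc_next = np.zeros((B, H), dtype=dout.dtype)
        for t in range(T - 1, -1, -1):
            i, f = gates[:, t, :H], gates[:, t, H:2 * H]
            g, o = gates[:, t, 2 * H:3 * H], gates[:, t, 3 * H:]
            c = cs[:, t]
            c_prev = cs[:, t - 1] if t > 0 else np.zeros_like(c)
            tc = np.tanh(c)
            dh = dh_seq[:, t] + dh_next
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g * i * (1.0 - i)
            df = dc * c_prev * f * (1.0 - f)
            dg = dc * i * (1.0 - g * g)
            do = dh * tc * o * (1.0 - o)
            dz = np.concatenate([di, df, dg, do], axis=1)
            dz_all[:, t] = dz
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        dz_flat = dz_all.reshape(-1, 4 * H)
        self.dWx[...] = x.reshape(-1, C).T @ dz_flat
        self.db[...] = dz_flat.sum(axis=0)
        dWh = np.zeros_like(self.Wh)
        for t in range(1, T):
            dWh += hs[:, t - 1].T @ dz_all[:, t]
        self.dWh[...] = dWh
        return (dz_flat @ self.Wx.T).reshape(B, T, C)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=_F):
        self.W = _glorot(rng, (c_in, c_out), dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy of integer targets; returns (loss, dlogits, probs)."""
    B = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -np.log(probs[np.arange(B), y] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    return loss, dlogits.astype(logits.dtype), probs


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(int(p.size) for p, _ in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(weights) != len(own):
            raise ValueError("weight list does not match model")
        for (p, _), w in zip(own, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {w.shape}")
            p[...] = w.astype(p.dtype)


class Adam:
    """Adam with optional global-norm gradient clipping."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7, clip_norm: float | None = 5.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        grads = [g for _, g in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = _F(self.clip_norm / (total + 1e-12))
                for g in grads:
                    g *= scale
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
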