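"""Trainable layers with hand-derived backward passes.

All layers operate on float32 batches: convolutional inputs are
``(batch, length, channels)``, dense inputs ``(..., features)``.  Each
layer owns its parameters and gradients in dicts keyed by name, caches
what its backward pass needs during ``forward(..., training=True)``, and
returns the input gradient from ``backward``.  Gradient correctness is
pinned down by numerical-differentiation tests.
"""

from __future__ import annotations

import numpy as np

from .functional import positional_encoding

DTYPE = np.float32


class Layer:
    """Base class: parameter/gradient dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict = {}
        self.grads: dict = {}

    def forward(self, x, training: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padding stride-1 1D convolution via im2col."""

    def __init__(self, kernel: int, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.kernel, self.c_in, self.c_out = kernel, c_in, c_out
        self.params = {
            "w": (rng.standard_normal((kernel, c_in, c_out)) * scale).astype(DTYPE),
            "b": np.zeros(c_out, dtype=DTYPE),
        }
        self.left = (kernel - 1) // 2

    def forward(self, x, training=False):
        B, l, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        if self.kernel > l:
            raise ValueError(f"kernel {self.kernel} longer than sequence {l}")
        L = self.kernel
        padded = np.pad(x, ((0, 0), (self.left, L - 1 - self.left), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(padded, L, axis=1)  # (B,l,C,L)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, l, L * c)
        self._cols, self._l = cols, l
        wmat = self.params["w"].reshape(L * c, self.c_out)
        return cols @ wmat + self.params["b"]

    def backward(self, dy):
        B, l, _ = dy.shape
        L, c = self.kernel, self.c_in
        wmat = self.params["w"].reshape(L * c, self.c_out)
        self.grads["w"] = np.einsum(
            "bik,bio->ko", self._cols, dy, optimize=True
        ).reshape(L, c, self.c_out)
        self.grads["b"] = dy.sum(axis=(0, 1))
        dcols = (dy @ wmat.T).reshape(B, l, L, c)
        dxp = np.zeros((B, l + L - 1, c), dtype=DTYPE)
        for k in range(L):
            dxp[:, k : k + l, :] += dcols[:, :, k, :]
        self._cols = None
        return dxp[:, self.left : self.left + l, :]


class BatchNorm1D(Layer):
    """Batch norm over (batch, time) per channel; momentum-0.99 running
    moments for inference."""

    def __init__(self, c: int, momentum: float = 0.99, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(c, dtype=DTYPE), "beta": np.zeros(c, dtype=DTYPE)}
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(DTYPE)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._xhat, self._inv, self._m = xhat, inv, x.shape[0] * x.shape[1]
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        xhat, inv, m = self._xhat, self._inv, self._m
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1))
        self.grads["beta"] = dy.sum(axis=(0, 1))
        dxhat = dy * self.params["gamma"]
        dx = (
            dxhat - dxhat.mean(axis=(0, 1)) - xhat * (dxhat * xhat).sum(axis=(0, 1)) / m
        ) * inv
        self._xhat = None
        return dx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time (trailing remainder dropped)."""

    def __init__(self, pool: int):
        super().__init__()
        if pool < 1:
            raise ValueError("pool must be >= 1")
        self.pool = pool

    def forward(self, x, training=False):
        if self.pool == 1:
            self._shape = None
            return x
        B, l, c = x.shape
        if self.pool > l:
            raise ValueError(f"pool {self.pool} exceeds sequence length {l}")
        n = l // self.pool
        blocks = x[:, : n * self.pool].reshape(B, n, self.pool, c)
        self._idx = blocks.argmax(axis=2)
        self._shape = (B, l, c, n)
        return blocks.max(axis=2)

    def backward(self, dy):
        if self._shape is None:
            return dy
        B, l, c, n = self._shape
        dx = np.zeros((B, n, self.pool, c), dtype=DTYPE)
        np.put_along_axis(dx, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        out = np.zeros((B, l, c), dtype=DTYPE)
        out[:, : n * self.pool] = dx.reshape(B, n * self.pool, c)
        return out


class Dense(Layer):
    """Affine map on the trailing axis (used both position-wise and on
    flat feature vectors)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, relu_init=True):
        super().__init__()
        scale = np.sqrt((2.0 if relu_init else 1.0) / d_in)
        self.params = {
            "w": (rng.standard_normal((d_in, d_out)) * scale).astype(DTYPE),
            "b": np.zeros(d_out, dtype=DTYPE),
        }

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy):
        x = self._x
        self.grads["w"] = np.tensordot(x, dy, axes=(range(x.ndim - 1), range(x.ndim - 1)))
        self.grads["b"] = dy.sum(axis=tuple(range(dy.ndim - 1)))
        self._x = None
        return dy @ self.params["w"].T


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return (x * self._mask).astype(DTYPE)

    def backward(self, dy):
        return dy if self._mask is None else (dy * self._mask).astype(DTYPE)


class LayerNorm(Layer):
    """Normalization over the feature axis with learnable scale/shift."""

    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(d, dtype=DTYPE), "beta": np.zeros(d, dtype=DTYPE)}
        self.eps = eps

    def forward(self, x, training=False):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat, self._inv = (x - mu) * inv, inv
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        d = xhat.shape[-1]
        axes = tuple(range(dy.ndim - 1))
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"]
        dx = (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        ) * inv
        self._xhat = None
        return dx.astype(DTYPE)


class AddPositionalEncoding(Layer):
    """Adds the fixed sinusoidal encoding; identity in backward."""

    def __init__(self):
        super().__init__()
        self._pe = None

    def forward(self, x, training=False):
        _, l, d = x.shape
        if self._pe is None or self._pe.shape != (l, d):
            self._pe = positional_encoding(l, d).astype(DTYPE)
        return x + self._pe

    def backward(self, dy):
        return dy


def _softmax_last(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadAttention(Layer):
    """h-head scaled dot-product self-attention with output projection.

    Head projections are stored as combined ``(d, d)`` matrices and split
    by reshape; with h heads each effectively has d/h-dimensional
    query/key/value spaces.  Setting ``capture`` stores the last softmax
    weight tensor ``(batch, heads, l, l)`` for interpretability analysis.
    """

    def __init__(self, d: int, h: int, rng: np.random.Generator):
        super().__init__()
        if d % h != 0:
            raise ValueError(
                f"head count {h} must divide the feature dimension {d} "
                "for equal division of attention"
            )
        self.d, self.h, self.dk = d, h, d // h
        scale = np.sqrt(1.0 / d)
        self.params = {
            name: (rng.standard_normal((d, d)) * scale).astype(DTYPE)
            for name in ("wq", "wk", "wv", "wo")
        }
        self.capture = False
        self.last_attention = None

    def _split(self, x):  # (B,l,d) -> (B,h,l,dk)
        B, l, _ = x.shape
        return x.reshape(B, l, self.h, self.dk).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (B,h,l,dk) -> (B,l,d)
        B, h, l, dk = x.shape
        return np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(B, l, h * dk)

    def forward(self, x, training=False):
        p = self.params
        Q = self._split(x @ p["wq"])
        K = self._split(x @ p["wk"])
        V = self._split(x @ p["wv"])
        scores = Q @ K.transpose(0, 1, 3, 2) / np.sqrt(self.dk)
        P = _softmax_last(scores).astype(DTYPE)
        ctx = self._merge(P @ V)
        if self.capture:
            self.last_attention = P.copy()
        self._cache = (x, Q, K, V, P, ctx)
        return ctx @ p["wo"]

    def backward(self, dy):
        x, Q, K, V, P, ctx = self._cache
        p = self.params
        self.grads["wo"] = np.tensordot(ctx, dy, axes=((0, 1), (0, 1)))
        dctx = self._split(dy @ p["wo"].T)
        dP = dctx @ V.transpose(0, 1, 3, 2)
        dV = P.transpose(0, 1, 3, 2) @ dctx
        dS = P * (dP - (dP * P).sum(axis=-1, keepdims=True))
        dS /= np.sqrt(self.dk)
        dQ = dS @ K
        dK = dS.transpose(0, 1, 3, 2) @ Q
        dq, dk_, dv = (self._merge(m) for m in (dQ, dK, dV))
        for name, g in (("wq", dq), ("wk", dk_), ("wv", dv)):
            self.grads[name] = np.tensordot(x, g, axes=((0, 1), (0, 1)))
        dx = dq @ p["wq"].T + dk_ @ p["wk"].T + dv @ p["wv"].T
        self._cache = None
        return dx.astype(DTYPE)


class EncoderLayer(Layer):
    """Post-norm Transformer encoder layer with optional ablations:
    ``Z_mid = LN(Z + MHA(Z)); O = LN(Z_mid + FFN(Z_mid))``."""

    def __init__(
        self,
        d: int,
        d_ff: int,
        h: int,
        rng: np.random.Generator,
        residual: bool = True,
        use_ffn: bool = True,
    ):
        super().__init__()
        self.mha = MultiHeadAttention(d, h, rng)
        self.ln1 = LayerNorm(d)
        self.residual, self.use_ffn = residual, use_ffn
        if use_ffn:
            self.fc1 = Dense(d, d_ff, rng)
            self.relu = ReLU()
            self.fc2 = Dense(d_ff, d, rng, relu_init=False)
            self.ln2 = LayerNorm(d)

    @property
    def sublayers(self):
        subs = [self.mha, self.ln1]
        if self.use_ffn:
            subs += [self.fc1, self.fc2, self.ln2]
        return subs

    def forward(self, x, training=False):
        a = self.mha.forward(x, training)
        z1 = self.ln1.forward(x + a if self.residual else a, training)
        if not self.use_ffn:
            return z1
        f = self.fc2.forward(
            self.relu.forward(self.fc1.forward(z1, training), training), training
        )
        return self.ln2.forward(z1 + f if self.residual else f, training)

    def backward(self, dy):
        if self.use_ffn:
            dz = self.ln2.backward(dy)
            df = self.fc1.backward(self.relu.backward(self.fc2.backward(dz)))
            dz1 = dz + df if self.residual else df
        else:
            dz1 = dy
        da = self.ln1.backward(dz1)
        dx = self.mha.backward(da)
        return (da + dx if self.residual else dx).astype(DTYPE)


class GlobalAveragePool(Layer):
    """Mean over the time axis: (B, l, d) -> (B, d)."""

    def forward(self, x, training=False):
        if x.shape[1] < 1:
            raise ValueError("cannot pool an empty sequence")
        self._l = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._l, axis=1) / self._l


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class LSTM(Layer):
    """Single-layer LSTM returning the full hidden-state sequence."""

    def __init__(self, c_in: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.units = c_in, units
        sw = np.sqrt(1.0 / c_in)
        su = np.sqrt(1.0 / units)
        self.params = {
            "w": (rng.standard_normal((c_in, 4 * units)) * sw).astype(DTYPE),
            "u": (rng.standard_normal((units, 4 * units)) * su).astype(DTYPE),
            "b": np.zeros(4 * units, dtype=DTYPE),
        }

    def forward(self, x, training=False):
        B, l, _ = x.shape
        U = self.units
        p = self.params
        h = np.zeros((B, U), dtype=DTYPE)
        c = np.zeros((B, U), dtype=DTYPE)
        pre = x @ p["w"] + p["b"]  # (B, l, 4U)
        hs = np.empty((B, l, U), dtype=DTYPE)
        cache = []
        for t in range(l):
            z = pre[:, t] + h @ p["u"]
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U : 2 * U])
            g = np.tanh(z[:, 2 * U : 3 * U])
            o = _sigmoid(z[:, 3 * U :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, t] = h
        self._cache = (x, hs, cache)
        return hs

    def backward(self, dy):
        x, hs, cache = self._cache
        B, l, _ = x.shape
        U = self.units
        p = self.params
        dw = np.zeros_like(p["w"])
        du = np.zeros_like(p["u"])
        db = np.zeros_like(p["b"])
        dx = np.empty_like(x)
        dh_next = np.zeros((B, U), dtype=DTYPE)
        dc_next = np.zeros((B, U), dtype=DTYPE)
        for t in reversed(range(l)):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = dy[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            ).astype(DTYPE)
            dw += x[:, t].T @ dz
            du += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ p["w"].T
            dh_next = dz @ p["u"].T
            dc_next = dc * f
        self.grads = {"w": dw, "u": du, "b": db}
        self._cache = None
        return dx


class AdditiveAttentionPool(Layer):
    """Additive (Bahdanau-style) attention pooling of a sequence:
    ``e_t = v . tanh(h_t W + b)``, softmax over t, weighted sum."""

    def __init__(self, d: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(1.0 / d)
        self.params = {
            "w": (rng.standard_normal((d, d)) * scale).astype(DTYPE),
            "b": np.zeros(d, dtype=DTYPE),
            "v": (rng.standard_normal(d) * scale).astype(DTYPE),
        }

    def forward(self, x, training=False):
        p = self.params
        u = np.tanh(x @ p["w"] + p["b"])  # (B,l,d)
        e = u @ p["v"]  # (B,l)
        alpha = _softmax_last(e).astype(DTYPE)
        self._cache = (x, u, alpha)
        return np.einsum("bl,bld->bd", alpha, x)

    def backward(self, dy):
        x, u, alpha = self._cache
        p = self.params
        dalpha = np.einsum("bd,bld->bl", dy, x)
        dx = alpha[:, :, None] * dy[:, None, :]
        de = alpha * (dalpha - (dalpha * alpha).sum(axis=-1, keepdims=True))
        dv = np.einsum("bl,bld->d", de, u)
        du = de[:, :, None] * p["v"]
        dpre = du * (1 - u**2)
        self.grads = {
            "w": np.tensordot(x, dpre, axes=((0, 1), (0, 1))),
            "b": dpre.sum(axis=(0, 1)),
            "v": dv,
        }
        dx += dpre @ p["w"].T
        self._cache = None
        return dx.astype(DTYPE)
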