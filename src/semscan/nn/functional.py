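"""Pure, independently testable layer primitives.

Every function here operates on a single feature sequence — a matrix of
shape ``(l, d)`` (sequence length x feature dimension) — with explicit
parameter containers and no hidden state.  They define the reference
semantics of the network; the trainable layers in :mod:`semscan.nn.layers`
must agree with them (and with brute-force loop oracles) to 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConvLayerParams",
    "MHAParams",
    "FFNParams",
    "LayerNormParams",
    "EncoderLayerParams",
    "conv1d_bn_relu",
    "max_pool",
    "positional_encoding",
    "scaled_dot_product_attention",
    "multi_head_attention",
    "feed_forward",
    "layer_norm",
    "encoder_layer",
    "global_average_pool",
]


@dataclass
class ConvLayerParams:
    """One convolutional layer: kernels of length L and width C (the input
    channel count), plus inference-mode batch-norm statistics."""

    weights: np.ndarray  # (L, C_in, C_out)
    bias: np.ndarray  # (C_out,)
    bn_gamma: np.ndarray | None = None
    bn_beta: np.ndarray | None = None
    bn_mean: np.ndarray | None = None
    bn_var: np.ndarray | None = None
    bn_eps: float = 1e-5


@dataclass
class MHAParams:
    """Per-head projection matrices W_q/W_k/W_v (each ``(d, d_k)``) and the
    output projection ``(h*d_v, d)``."""

    w_q: Sequence
    w_k: Sequence
    w_v: Sequence
    w_o: np.ndarray


@dataclass
class FFNParams:
    w1: np.ndarray  # (d, d_ff)
    b1: np.ndarray
    w2: np.ndarray  # (d_ff, d)
    b2: np.ndarray


@dataclass
class LayerNormParams:
    gamma: np.ndarray
    beta: np.ndarray
    eps: float = 1e-5


@dataclass
class EncoderLayerParams:
    mha: MHAParams
    ffn: FFNParams
    ln1: LayerNormParams
    ln2: LayerNormParams
    n_heads: int = 2


def conv1d_bn_relu(x: np.ndarray, params: ConvLayerParams) -> np.ndarray:
    """Same-padding stride-1 1D convolution, then batch norm (inference
    moments), then ReLU.  ``x`` has shape ``(l, C_in)``."""
    x = np.asarray(x, dtype=float)
    L, c_in, c_out = params.weights.shape
    l = x.shape[0]
    if x.ndim != 2 or x.shape[1] != c_in:
        raise ValueError(f"input shape {x.shape} incompatible with kernel width {c_in}")
    if L > l:
        raise ValueError(f"kernel length {L} exceeds sequence length {l}")
    left = (L - 1) // 2
    padded = np.pad(x, ((left, L - 1 - left), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(padded, L, axis=0)  # (l, C_in, L)
    y = np.einsum("jcl,lco->jo", windows, params.weights) + params.bias
    if params.bn_gamma is not None:
        y = (y - params.bn_mean) / np.sqrt(params.bn_var + params.bn_eps)
        y = params.bn_gamma * y + params.bn_beta
    return np.maximum(y, 0.0)


def max_pool(x: np.ndarray, pool: int) -> np.ndarray:
    """Per-channel maximum over non-overlapping windows of ``pool`` steps."""
    x = np.asarray(x, dtype=float)
    l = x.shape[0]
    if pool < 1:
        raise ValueError("pool must be >= 1")
    if pool > l:
        raise ValueError(f"pool {pool} exceeds sequence length {l}")
    n_out = l // pool
    return x[: n_out * pool].reshape(n_out, pool, -1).max(axis=1)


def positional_encoding(l: int, d: int) -> np.ndarray:
    """Fixed sinusoidal encoding: PE(pos, 2i) = sin(pos / 10000^(2i/d)),
    PE(pos, 2i+1) = cos(pos / 10000^(2i/d))."""
    if l < 1 or d < 1:
        raise ValueError("l and d must be >= 1")
    if d % 2 != 0:
        raise ValueError("feature dimension must be even")
    pos = np.arange(l)[:, None]
    i = np.arange(d // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / d)
    pe = np.empty((l, d))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def scaled_dot_product_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray):
    """``Softmax(Q K^T / sqrt(d_k)) V``; returns (output, weight matrix)."""
    Q, K, V = (np.asarray(m, dtype=float) for m in (Q, K, V))
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError(f"Q and K dimensions differ: {Q.shape[-1]} vs {K.shape[-1]}")
    if K.shape[0] != V.shape[0]:
        raise ValueError(f"K and V lengths differ: {K.shape[0]} vs {V.shape[0]}")
    d_k = Q.shape[-1]
    weights = _softmax(Q @ K.T / np.sqrt(d_k), axis=-1)
    return weights @ V, weights


def multi_head_attention(Z: np.ndarray, params: MHAParams, h: int = 2) -> np.ndarray:
    """Per-head attention on ``d/h``-dimensional projections, concatenated
    and projected by W_o."""
    Z = np.asarray(Z, dtype=float)
    d = Z.shape[1]
    if d % h != 0:
        raise ValueError(f"head count {h} must divide feature dimension {d}")
    if len(params.w_q) != h:
        raise ValueError(f"expected {h} per-head projections, got {len(params.w_q)}")
    heads = []
    for wq, wk, wv in zip(params.w_q, params.w_k, params.w_v):
        out, _ = scaled_dot_product_attention(Z @ wq, Z @ wk, Z @ wv)
        heads.append(out)
    return np.concatenate(heads, axis=1) @ params.w_o


def feed_forward(x: np.ndarray, params: FFNParams) -> np.ndarray:
    """Position-wise two-layer network: ``max(0, x W1 + b1) W2 + b2``."""
    x = np.asarray(x, dtype=float)
    if x.shape[1] != params.w1.shape[0] or params.w1.shape[1] != params.w2.shape[0]:
        raise ValueError(
            f"inconsistent FFN shapes: x {x.shape}, W1 {params.w1.shape}, "
            f"W2 {params.w2.shape}"
        )
    return np.maximum(x @ params.w1 + params.b1, 0.0) @ params.w2 + params.b2


def layer_norm(x: np.ndarray, params: LayerNormParams) -> np.ndarray:
    """Normalization over the feature dimension with learnable scale/shift."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return params.gamma * (x - mu) / np.sqrt(var + params.eps) + params.beta


def encoder_layer(Z: np.ndarray, params: EncoderLayerParams) -> np.ndarray:
    """Post-norm encoder layer:
    ``Z_mid = LN(Z + MHA(Z)); O = LN(Z_mid + FFN(Z_mid))``."""
    z_mid = layer_norm(Z + multi_head_attention(Z, params.mha, params.n_heads), params.ln1)
    return layer_norm(z_mid + feed_forward(z_mid, params.ffn), params.ln2)


def global_average_pool(x: np.ndarray) -> np.ndarray:
    """Per-channel arithmetic mean over the time axis."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 1:
        raise ValueError("cannot pool an empty sequence")
    return x.mean(axis=0)
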