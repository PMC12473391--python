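"""Parallel two-branch network assembly: PMMCT and baselines.

Every variant shares the same skeleton — two parallel branches, one per
modality, each starting with a convolutional module (conv-BN-ReLU x2 with
max pooling), followed by a variant-specific temporal model, then a
pooling step that reduces the sequence to one feature vector; the two
vectors are concatenated and classified by FC(ReLU) -> dropout -> FC(2)
-> softmax:

* ``pmmct``: positional encoding + N post-norm Transformer encoder layers
  + global average pooling,
* ``cnn``: global average pooling directly after the conv module,
* ``cnn_lstm``: a single LSTM layer + global average pooling,
* ``cnn_lstm_attn``: a single LSTM layer + additive attention pooling.

Ablations of the pmmct variant: ``no_transformer`` (drop the encoder),
``no_cnn`` (replace the conv module by a position-wise linear projection
with the same total pooling), ``no_residual`` and ``no_ffn`` (degrade the
encoder layers).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .nn.layers import (
    DTYPE,
    AddPositionalEncoding,
    AdditiveAttentionPool,
    BatchNorm1D,
    Conv1D,
    Dense,
    Dropout,
    EncoderLayer,
    GlobalAveragePool,
    LSTM,
    MaxPool1D,
    ReLU,
)

__all__ = ["ModelConfig", "ParallelNet", "build_model", "VARIANTS", "ABLATIONS"]

VARIANTS = ("pmmct", "cnn", "cnn_lstm", "cnn_lstm_attn")
ABLATIONS = (None, "no_transformer", "no_cnn", "no_residual", "no_ffn")
GRID_KERNEL_SIZES = (50, 150, 250)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``kernel_sizes`` is the four-tuple (k1, k2, k3, k4): (k1, k2) are the
    two conv layers of the modality-1 branch, (k3, k4) of modality 2.
    ``pool_sizes`` gives each conv layer its pooling factor; (1, 4) puts a
    single pool-4 max-pooling after the second conv layer.
    """

    variant: str = "pmmct"
    kernel_sizes: tuple = (50, 50, 50, 50)
    d_model: int = 64
    n_heads: int = 2
    n_encoder_layers: int = 2
    d_ff: int = 128
    pool_sizes: tuple = (1, 4)
    lstm_units: int = 100
    fc_units: int = 64
    dropout: float = 0.5
    ablation: str | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}, got {self.ablation!r}")
        if self.ablation and self.variant != "pmmct":
            raise ValueError("ablations are defined for the pmmct variant only")
        if len(self.kernel_sizes) != 4:
            raise ValueError("kernel_sizes must be a four-tuple (k1, k2, k3, k4)")
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"the number of heads ({self.n_heads}) must divide the feature "
                f"dimension ({self.d_model}) for equal division of attention"
            )

    def to_dict(self) -> dict:
        return asdict(self)


class _Chain:
    """A plain sequence of layers with chained forward/backward."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def iter_layers(self):
        for layer in self.layers:
            if isinstance(layer, EncoderLayer):
                yield from layer.sublayers
            else:
                yield layer


def _conv_module(k1, k2, d, pools, rng):
    return [
        Conv1D(k1, 1, d, rng),
        BatchNorm1D(d),
        ReLU(),
        MaxPool1D(pools[0]),
        Conv1D(k2, d, d, rng),
        BatchNorm1D(d),
        ReLU(),
        MaxPool1D(pools[1]),
    ]


def _build_branch(cfg: ModelConfig, kernels, rng) -> _Chain:
    d = cfg.d_model
    ablation = cfg.ablation
    if ablation == "no_cnn":
        front = [Dense(1, d, rng), MaxPool1D(cfg.pool_sizes[0] * cfg.pool_sizes[1])]
    else:
        front = _conv_module(kernels[0], kernels[1], d, cfg.pool_sizes, rng)

    if cfg.variant == "cnn" or ablation == "no_transformer":
        return _Chain(front + [GlobalAveragePool()])
    if cfg.variant == "cnn_lstm":
        return _Chain(front + [LSTM(d, cfg.lstm_units, rng), GlobalAveragePool()])
    if cfg.variant == "cnn_lstm_attn":
        return _Chain(
            front
            + [LSTM(d, cfg.lstm_units, rng), AdditiveAttentionPool(cfg.lstm_units, rng)]
        )
    encoders = [
        EncoderLayer(
            d,
            cfg.d_ff,
            cfg.n_heads,
            rng,
            residual=ablation != "no_residual",
            use_ffn=ablation != "no_ffn",
        )
        for _ in range(cfg.n_encoder_layers)
    ]
    return _Chain(front + [AddPositionalEncoding()] + encoders + [GlobalAveragePool()])


class ParallelNet:
    """Two parallel branches, concatenation fusion, and the classifier head."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        feat = (
            config.lstm_units
            if config.variant in ("cnn_lstm", "cnn_lstm_attn")
            else config.d_model
        )
        self.branch1 = _build_branch(config, config.kernel_sizes[:2], rng)
        self.branch2 = _build_branch(config, config.kernel_sizes[2:], rng)
        self.head = _Chain(
            [
                Dense(2 * feat, config.fc_units, rng),
                ReLU(),
                Dropout(config.dropout, rng),
                Dense(config.fc_units, 2, rng, relu_init=False),
            ]
        )
        self.feat = feat

    # -- forward/backward ------------------------------------------------
    def forward(self, x1: np.ndarray, x2: np.ndarray, training: bool = False):
        """Logits for a batch: inputs are (B, win) per modality."""
        if x1.shape != x2.shape:
            raise ValueError("both modalities must share the batch shape")
        a = self.branch1.forward(x1[..., None].astype(DTYPE), training)
        b = self.branch2.forward(x2[..., None].astype(DTYPE), training)
        fused = np.concatenate([a, b], axis=1)  # (B, 2*feat)
        return self.head.forward(fused, training)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits)
        self.branch1.backward(dfused[:, : self.feat])
        self.branch2.backward(dfused[:, self.feat :])

    def predict_proba(self, x1, x2, batch_size: int = 256) -> np.ndarray:
        probs = []
        for i in range(0, len(x1), batch_size):
            logits = self.forward(x1[i : i + batch_size], x2[i : i + batch_size])
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            probs.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(probs)

    # -- parameter access ------------------------------------------------
    def iter_layers(self):
        yield from self.branch1.iter_layers()
        yield from self.branch2.iter_layers()
        yield from self.head.iter_layers()

    def parameters(self):
        """Yield (layer, name, array) triples for every trainable tensor."""
        for layer in self.iter_layers():
            for name in layer.params:
                yield layer, name, layer.params[name]

    def n_parameters(self) -> int:
        return sum(p.size for _, _, p in self.parameters())

    def get_weights(self) -> list:
        return [p.copy() for _, _, p in self.parameters()]

    def set_weights(self, weights) -> None:
        for (layer, name, _), w in zip(self.parameters(), weights):
            layer.params[name] = w.copy()

    # -- attention instrumentation ---------------------------------------
    def attention_layers(self, branch: int):
        chain = self.branch1 if branch == 0 else self.branch2
        return [lyr.mha for lyr in chain.layers if isinstance(lyr, EncoderLayer)]

    def set_attention_capture(self, flag: bool) -> None:
        mhas = self.attention_layers(0) + self.attention_layers(1)
        if not mhas:
            raise ValueError(
                "attention capture requires a Transformer-based variant; "
                f"{self.config.variant!r} with ablation {self.config.ablation!r} "
                "has no encoder layers"
            )
        for mha in mhas:
            mha.capture = flag


def build_model(config: ModelConfig, rng: np.random.Generator | int | None = None) -> ParallelNet:
    """Instantiate a network for the given configuration."""
    if config.ablation == "no_transformer" and config.variant != "pmmct":
        raise ValueError("no_transformer ablation applies to pmmct")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return ParallelNet(config, rng)
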