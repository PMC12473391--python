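"""Trainable layers: agreement with the functional primitives and
numerical-gradient verification of every backward pass."""

import numpy as np
import pytest

import semscan.architectures as architectures_mod
import semscan.nn.layers as layers_mod
from semscan.architectures import ModelConfig, build_model
from semscan.nn import functional as F
from semscan.nn.layers import (
    LSTM,
    AdditiveAttentionPool,
    BatchNorm1D,
    Conv1D,
    Dense,
    GlobalAveragePool,
    LayerNorm,
    MaxPool1D,
    MultiHeadAttention,
)


@pytest.fixture
def float64_layers(monkeypatch):
    """Run the layer stack in float64 so numerical gradients resolve."""
    monkeypatch.setattr(layers_mod, "DTYPE", np.float64)
    monkeypatch.setattr(architectures_mod, "DTYPE", np.float64)


class TestForwardAgreement:
    """Batched trainable layers must reproduce the pure primitives."""

    def test_conv_matches_functional(self):
        rng = np.random.default_rng(0)
        layer = Conv1D(5, 3, 4, rng)
        x = rng.standard_normal((2, 11, 3)).astype(np.float32)
        out = layer.forward(x)
        for b in range(2):
            p = F.ConvLayerParams(
                weights=layer.params["w"].astype(float), bias=layer.params["b"].astype(float)
            )
            # functional applies ReLU; recover the pre-activation via
            # relu(a) - relu(-a) = a with negated weights and bias
            expected = F.conv1d_bn_relu(x[b].astype(float), p) - F.conv1d_bn_relu(
                x[b].astype(float), F.ConvLayerParams(weights=-p.weights, bias=-p.bias)
            )
            assert np.allclose(out[b], expected, atol=1e-4)

    def test_maxpool_matches_functional(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 12, 2)).astype(np.float32)
        out = MaxPool1D(3).forward(x)
        for b in range(3):
            assert np.allclose(out[b], F.max_pool(x[b].astype(float), 3), atol=1e-6)

    def test_mha_matches_functional(self):
        rng = np.random.default_rng(2)
        d, h = 8, 2
        layer = MultiHeadAttention(d, h, rng)
        x = rng.standard_normal((2, 6, d)).astype(np.float32)
        out = layer.forward(x)
        dk = d // h
        p = F.MHAParams(
            w_q=[layer.params["wq"].astype(float)[:, i * dk : (i + 1) * dk] for i in range(h)],
            w_k=[layer.params["wk"].astype(float)[:, i * dk : (i + 1) * dk] for i in range(h)],
            w_v=[layer.params["wv"].astype(float)[:, i * dk : (i + 1) * dk] for i in range(h)],
            w_o=layer.params["wo"].astype(float),
        )
        for b in range(2):
            assert np.allclose(
                out[b], F.multi_head_attention(x[b].astype(float), p, h), atol=1e-4
            )

    def test_layernorm_matches_functional(self):
        rng = np.random.default_rng(3)
        layer = LayerNorm(6)
        layer.params["gamma"] = rng.standard_normal(6).astype(np.float32)
        layer.params["beta"] = rng.standard_normal(6).astype(np.float32)
        x = rng.standard_normal((2, 4, 6)).astype(np.float32)
        out = layer.forward(x)
        p = F.LayerNormParams(
            gamma=layer.params["gamma"].astype(float), beta=layer.params["beta"].astype(float)
        )
        for b in range(2):
            assert np.allclose(out[b], F.layer_norm(x[b].astype(float), p), atol=1e-5)

    def test_gap_matches_functional(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((2, 9, 5)).astype(np.float32)
        out = GlobalAveragePool().forward(x)
        for b in range(2):
            assert np.allclose(out[b], F.global_average_pool(x[b].astype(float)), atol=1e-6)


def _scalar_loss_grad(net, x1, x2, y):
    logits = net.forward(x1, x2, training=True)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    loss = -np.mean(np.log(p[np.arange(len(y)), y]))
    return loss, (p - np.eye(2)[y]) / len(y)


VARIANT_CONFIGS = [
    dict(variant="pmmct", kernel_sizes=(5, 5, 5, 5), d_model=8, n_heads=2,
         n_encoder_layers=2, d_ff=16, pool_sizes=(2, 2), fc_units=8, dropout=0.0),
    dict(variant="cnn", kernel_sizes=(5, 5, 5, 5), d_model=8, pool_sizes=(2, 2),
         fc_units=8, dropout=0.0),
    dict(variant="cnn_lstm", kernel_sizes=(5, 5, 5, 5), d_model=8, lstm_units=6,
         pool_sizes=(2, 2), fc_units=8, dropout=0.0),
    dict(variant="cnn_lstm_attn", kernel_sizes=(5, 5, 5, 5), d_model=8, lstm_units=6,
         pool_sizes=(2, 2), fc_units=8, dropout=0.0),
    dict(variant="pmmct", ablation="no_cnn", d_model=8, n_heads=2, pool_sizes=(2, 2),
         fc_units=8, dropout=0.0),
    dict(variant="pmmct", ablation="no_residual", kernel_sizes=(5, 5, 5, 5), d_model=8,
         pool_sizes=(2, 2), fc_units=8, dropout=0.0),
    dict(variant="pmmct", ablation="no_ffn", kernel_sizes=(5, 5, 5, 5), d_model=8,
         pool_sizes=(2, 2), fc_units=8, dropout=0.0),
]


@pytest.mark.parametrize("kwargs", VARIANT_CONFIGS,
                         ids=lambda k: f"{k['variant']}-{k.get('ablation')}")
def test_backward_matches_numerical_gradient(kwargs, float64_layers):
    """Every parameter gradient of every variant agrees with central
    differences (absolute floor covers near-zero gradients such as conv
    biases that batch norm absorbs)."""
    cfg = ModelConfig(**kwargs)
    net = build_model(cfg, np.random.default_rng(1))
    for layer, name, p in net.parameters():
        layer.params[name] = p.astype(np.float64)
    rng = np.random.default_rng(0)
    x1 = rng.standard_normal((3, 24))
    x2 = rng.standard_normal((3, 24))
    y = np.array([0, 1, 0])
    _, dlogits = _scalar_loss_grad(net, x1, x2, y)
    net.backward(dlogits)
    grads = {
        (id(layer), name): layer.grads[name].copy() for layer, name, _ in net.parameters()
    }
    eps = 1e-6
    for layer, name, param in net.parameters():
        flat = param.ravel()
        idxs = rng.choice(flat.size, size=min(4, flat.size), replace=False)
        for i in idxs:
            orig = flat[i]
            flat[i] = orig + eps
            lp, _ = _scalar_loss_grad(net, x1, x2, y)
            flat[i] = orig - eps
            lm, _ = _scalar_loss_grad(net, x1, x2, y)
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[(id(layer), name)].ravel()[i]
            assert abs(num - ana) <= 1e-5 + 1e-3 * (abs(num) + abs(ana)), (
                f"{type(layer).__name__}.{name}: numerical {num} vs analytic {ana}"
            )


def test_lstm_backward_numerical(float64_layers):
    rng = np.random.default_rng(0)
    lstm = LSTM(3, 4, rng)
    for k, v in lstm.params.items():
        lstm.params[k] = v.astype(np.float64)
    x = rng.standard_normal((2, 6, 3))

    def loss():
        return float((lstm.forward(x) ** 2).sum())

    out = lstm.forward(x)
    dx = lstm.backward(2 * out)
    eps = 1e-6
    xi = rng.choice(x.size, 6, replace=False)
    for i in xi:
        orig = x.ravel()[i]
        x.ravel()[i] = orig + eps
        lp = loss()
        x.ravel()[i] = orig - eps
        lm = loss()
        x.ravel()[i] = orig
        num = (lp - lm) / (2 * eps)
        assert abs(num - dx.ravel()[i]) <= 1e-4 + 1e-4 * abs(num)


def test_batchnorm_train_vs_inference():
    rng = np.random.default_rng(0)
    bn = BatchNorm1D(3, momentum=0.5)
    x = (rng.standard_normal((4, 10, 3)) * 2 + 1).astype(np.float32)
    out = bn.forward(x, training=True)
    # batch statistics: per-channel zero mean / unit variance (pre-affine)
    assert np.allclose(out.mean(axis=(0, 1)), 0.0, atol=1e-5)
    assert np.allclose(out.std(axis=(0, 1)), 1.0, atol=1e-3)
    # running moments move toward the batch statistics
    for _ in range(20):
        bn.forward(x, training=True)
    inf = bn.forward(x, training=False)
    assert np.allclose(inf.mean(axis=(0, 1)), 0.0, atol=0.05)


def test_dropout_inference_identity_and_training_scale():
    rng = np.random.default_rng(0)
    from semscan.nn.layers import Dropout

    drop = Dropout(0.5, rng)
    x = np.ones((200, 10), dtype=np.float32)
    assert np.array_equal(drop.forward(x, training=False), x)
    out = drop.forward(x, training=True)
    assert set(np.unique(out)) <= {0.0, 2.0}
    assert out.mean() == pytest.approx(1.0, abs=0.1)
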