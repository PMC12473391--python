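"""Layer primitives against brute-force loop oracles and closed forms."""

import numpy as np
import pytest

from semscan.nn.functional import (
    ConvLayerParams,
    EncoderLayerParams,
    FFNParams,
    LayerNormParams,
    MHAParams,
    conv1d_bn_relu,
    encoder_layer,
    feed_forward,
    global_average_pool,
    layer_norm,
    max_pool,
    multi_head_attention,
    positional_encoding,
    scaled_dot_product_attention,
)

# ---------------------------------------------------------------------------
# brute-force oracles


def conv_oracle(x, w, b):
    """Direct sliding dot-product with same padding."""
    L, c_in, c_out = w.shape
    l = x.shape[0]
    left = (L - 1) // 2
    xp = np.pad(x, ((left, L - 1 - left), (0, 0)))
    out = np.zeros((l, c_out))
    for j in range(l):
        for o in range(c_out):
            out[j, o] = np.sum(xp[j : j + L] * w[:, :, o]) + b[o]
    return out


def sdpa_oracle(Q, K, V):
    lq, d = Q.shape
    lk = K.shape[0]
    W = np.zeros((lq, lk))
    for i in range(lq):
        scores = np.array([Q[i] @ K[j] / np.sqrt(d) for j in range(lk)])
        e = np.exp(scores - scores.max())
        W[i] = e / e.sum()
    return W @ V, W


def _rng_params(rng, d, h, d_ff):
    dk = d // h
    mha = MHAParams(
        w_q=[rng.standard_normal((d, dk)) for _ in range(h)],
        w_k=[rng.standard_normal((d, dk)) for _ in range(h)],
        w_v=[rng.standard_normal((d, dk)) for _ in range(h)],
        w_o=rng.standard_normal((d, d)),
    )
    ffn = FFNParams(
        w1=rng.standard_normal((d, d_ff)),
        b1=rng.standard_normal(d_ff),
        w2=rng.standard_normal((d_ff, d)),
        b2=rng.standard_normal(d),
    )
    ln = lambda: LayerNormParams(gamma=rng.standard_normal(d), beta=rng.standard_normal(d))
    return EncoderLayerParams(mha=mha, ffn=ffn, ln1=ln(), ln2=ln(), n_heads=h)


class TestConv:
    def test_identity_kernel_reduces_to_relu(self):
        x = np.array([[-1.0], [2.0], [-3.0], [4.0]])
        p = ConvLayerParams(weights=np.ones((1, 1, 1)), bias=np.zeros(1))
        assert np.allclose(conv1d_bn_relu(x, p), np.maximum(x, 0))

    def test_averaging_kernel_on_constant(self):
        x = np.full((10, 1), 5.0)
        p = ConvLayerParams(weights=np.full((3, 1, 1), 1 / 3), bias=np.zeros(1))
        assert np.allclose(conv1d_bn_relu(x, p)[1:-1], 5.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((8, 2))
        w = rng.standard_normal((3, 2, 4))
        b = rng.standard_normal(4)
        p = ConvLayerParams(weights=w, bias=b)
        assert np.allclose(conv1d_bn_relu(x, p), np.maximum(conv_oracle(x, w, b), 0), atol=1e-6)

    def test_bn_inference_moments_applied(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((6, 1))
        p = ConvLayerParams(
            weights=np.ones((1, 1, 1)), bias=np.zeros(1),
            bn_gamma=np.array([2.0]), bn_beta=np.array([1.0]),
            bn_mean=np.array([0.5]), bn_var=np.array([4.0]), bn_eps=0.0,
        )
        expected = np.maximum(2.0 * (x - 0.5) / 2.0 + 1.0, 0)
        assert np.allclose(conv1d_bn_relu(x, p), expected)

    def test_kernel_longer_than_sequence(self):
        p = ConvLayerParams(weights=np.ones((5, 1, 1)), bias=np.zeros(1))
        with pytest.raises(ValueError, match="kernel"):
            conv1d_bn_relu(np.zeros((3, 1)), p)


class TestMaxPool:
    def test_example(self):
        assert np.allclose(max_pool(np.array([[1.0], [3.0], [2.0], [5.0]]), 2), [[3.0], [5.0]])

    def test_constant(self):
        assert np.all(max_pool(np.full((8, 3), 2.0), 4) == 2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((12, 3))
        out = max_pool(x, 3)
        for i in range(4):
            assert np.allclose(out[i], x[3 * i : 3 * i + 3].max(axis=0))

    def test_pool_exceeding_length(self):
        with pytest.raises(ValueError, match="pool"):
            max_pool(np.zeros((3, 1)), 5)


class TestPositionalEncoding:
    def test_position_zero(self):
        pe = positional_encoding(4, 6)
        assert np.allclose(pe[0, 0::2], 0.0)
        assert np.allclose(pe[0, 1::2], 1.0)

    def test_bounded(self):
        pe = positional_encoding(50, 16)
        assert np.all(np.abs(pe) <= 1.0)

    def test_closed_form_value(self):
        pe = positional_encoding(2, 4)
        assert pe[1, 0] == pytest.approx(np.sin(1.0), abs=1e-12)
        assert pe[1, 1] == pytest.approx(np.cos(1.0), abs=1e-12)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError, match="even"):
            positional_encoding(4, 5)


class TestScaledDotProductAttention:
    def test_singleton_key(self):
        out, w = scaled_dot_product_attention(
            np.ones((3, 2)), np.ones((1, 2)), np.array([[5.0, 6.0]])
        )
        assert np.allclose(w, 1.0)
        assert np.allclose(out, [[5.0, 6.0]] * 3)

    def test_identical_keys_uniform_weights(self):
        rng = np.random.default_rng(0)
        K = np.tile(rng.standard_normal(4), (5, 1))
        _, w = scaled_dot_product_attention(rng.standard_normal((3, 4)), K, rng.standard_normal((5, 2)))
        assert np.allclose(w, 1 / 5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Q, K, V = (rng.standard_normal((4, 8)) for _ in range(3))
        out, w = scaled_dot_product_attention(Q, K, V)
        out_o, w_o = sdpa_oracle(Q, K, V)
        assert np.allclose(out, out_o, atol=1e-6)
        assert np.allclose(w, w_o, atol=1e-6)

    def test_rows_stochastic(self):
        rng = np.random.default_rng(1)
        _, w = scaled_dot_product_attention(*(rng.standard_normal((6, 4)) for _ in range(3)))
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(w >= 0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimensions"):
            scaled_dot_product_attention(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 4)))


class TestMultiHeadAttention:
    def test_single_identity_head_reduces_to_sdpa(self):
        rng = np.random.default_rng(2)
        Z = rng.standard_normal((5, 4))
        eye = np.eye(4)
        p = MHAParams(w_q=[eye], w_k=[eye], w_v=[eye], w_o=eye)
        expected, _ = scaled_dot_product_attention(Z, Z, Z)
        assert np.allclose(multi_head_attention(Z, p, h=1), expected, atol=1e-12)

    def test_output_shape_preserved(self):
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((7, 8))
        p = _rng_params(rng, 8, 2, 16).mha
        assert multi_head_attention(Z, p, h=2).shape == Z.shape

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_manual_two_head_computation(self, seed):
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((6, 8))
        p = _rng_params(rng, 8, 2, 16).mha
        heads = []
        for i in range(2):
            out, _ = sdpa_oracle(Z @ p.w_q[i], Z @ p.w_k[i], Z @ p.w_v[i])
            heads.append(out)
        expected = np.concatenate(heads, axis=1) @ p.w_o
        assert np.allclose(multi_head_attention(Z, p, h=2), expected, atol=1e-6)

    def test_indivisible_heads_rejected(self):
        rng = np.random.default_rng(0)
        p = _rng_params(rng, 8, 2, 16).mha
        with pytest.raises(ValueError, match="divide"):
            multi_head_attention(np.zeros((4, 9)), p, h=2)


class TestFeedForward:
    def test_identity_on_nonnegative(self):
        x = np.abs(np.random.default_rng(0).standard_normal((4, 3)))
        p = FFNParams(w1=np.eye(3), b1=np.zeros(3), w2=np.eye(3), b2=np.zeros(3))
        assert np.allclose(feed_forward(x, p), x)

    def test_position_wise_locality(self):
        rng = np.random.default_rng(1)
        p = FFNParams(
            w1=rng.standard_normal((3, 6)), b1=rng.standard_normal(6),
            w2=rng.standard_normal((6, 3)), b2=rng.standard_normal(3),
        )
        x = rng.standard_normal((5, 3))
        x2 = x.copy()
        x2[2] += 1.0
        diff = feed_forward(x2, p) - feed_forward(x, p)
        assert np.allclose(diff[[0, 1, 3, 4]], 0.0)
        assert not np.allclose(diff[2], 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_explicit_algebra(self, seed):
        rng = np.random.default_rng(seed)
        p = FFNParams(
            w1=rng.standard_normal((4, 8)), b1=rng.standard_normal(8),
            w2=rng.standard_normal((8, 4)), b2=rng.standard_normal(4),
        )
        x = rng.standard_normal((6, 4))
        expected = np.maximum(x @ p.w1 + p.b1, 0) @ p.w2 + p.b2
        assert np.allclose(feed_forward(x, p), expected, atol=1e-12)

    def test_shape_mismatch(self):
        p = FFNParams(w1=np.eye(3), b1=np.zeros(3), w2=np.eye(4), b2=np.zeros(4))
        with pytest.raises(ValueError, match="shapes"):
            feed_forward(np.zeros((2, 3)), p)


class TestEncoderLayer:
    def test_output_normalized_per_position(self):
        rng = np.random.default_rng(4)
        d = 8
        p = _rng_params(rng, d, 2, 16)
        p.ln2.gamma = np.ones(d)
        p.ln2.beta = np.zeros(d)
        out = encoder_layer(rng.standard_normal((5, d)), p)
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(out.var(axis=1), 1.0, atol=1e-4)

    def test_shape_preserved(self):
        rng = np.random.default_rng(5)
        Z = rng.standard_normal((9, 8))
        assert encoder_layer(Z, _rng_params(rng, 8, 2, 16)).shape == Z.shape

    @pytest.mark.parametrize("seed", range(5))
    def test_composition_matches_sub_operations(self, seed):
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((6, 8))
        p = _rng_params(rng, 8, 2, 16)
        z_mid = layer_norm(Z + multi_head_attention(Z, p.mha, 2), p.ln1)
        expected = layer_norm(z_mid + feed_forward(z_mid, p.ffn), p.ln2)
        assert np.allclose(encoder_layer(Z, p), expected, atol=1e-12)


class TestGlobalAveragePool:
    def test_constant_channel(self):
        assert np.allclose(global_average_pool(np.full((7, 3), 4.2)), 4.2)

    def test_simple_mean(self):
        assert global_average_pool(np.array([[1.0], [2.0], [3.0]]))[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_time_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((10, 4))
        perm = rng.permutation(10)
        assert np.allclose(global_average_pool(x), global_average_pool(x[perm]), atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            global_average_pool(np.zeros((0, 3)))
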