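"""Attention gates against hand-evaluated and loop oracles."""

import numpy as np
import pytest

from csag.attention import (
    AttentionFusion,
    ChannelAttention,
    SpatialAttention,
    channel_attention,
    csfag_attention_fusion,
    spatial_attention,
)
from csag.nn import Tensor


def _identity_channel_mlp(c):
    """rho=1 module with W=I, b=0 in both layers (identity on >=0 inputs)."""
    m = ChannelAttention(c, ratio=1, dtype=np.float64)
    m.fc1.weight.data = np.eye(c)
    m.fc1.bias.data = np.zeros(c)
    m.fc2.weight.data = np.eye(c)
    m.fc2.bias.data = np.zeros(c)
    return m


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestChannelAttention:
    def test_zero_input_identity_mlp_gives_half(self):
        state, _ = channel_attention(np.zeros((1, 4, 4)), module=_identity_channel_mlp(1))
        np.testing.assert_allclose(state.weights, [0.5])

    def test_two_channel_hand_values(self):
        x = np.stack([np.ones((3, 3)), np.zeros((3, 3))])
        state, gated = channel_attention(x, module=_identity_channel_mlp(2))
        np.testing.assert_allclose(state.logits, [2.0, 0.0])
        np.testing.assert_allclose(state.weights, [_sigmoid(2.0), 0.5], atol=1e-12)
        np.testing.assert_allclose(gated[0], _sigmoid(2.0))

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 8, 8))
        module = ChannelAttention(4, ratio=2, rng=np.random.default_rng(7), dtype=np.float64)
        state, gated = channel_attention(x, module=module)
        # independent recomputation: pool -> two matrix products -> sum -> sigmoid
        w1, b1 = module.fc1.weight.data, module.fc1.bias.data
        w2, b2 = module.fc2.weight.data, module.fc2.bias.data

        def mlp(v):
            return np.maximum(v @ w1 + b1, 0.0) @ w2 + b2

        avg = np.array([x[c].mean() for c in range(4)])
        mx = np.array([x[c].max() for c in range(4)])
        expected = _sigmoid(mlp(avg) + mlp(mx))
        np.testing.assert_allclose(state.weights, expected, atol=1e-6)
        np.testing.assert_allclose(gated, x * expected[:, None, None], atol=1e-6)

    def test_pooled_avg_below_pooled_max(self):
        rng = np.random.default_rng(3)
        state, _ = channel_attention(rng.standard_normal((5, 6, 6)), rho=1)
        assert np.all(state.pooled_avg <= state.pooled_max)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            channel_attention(np.zeros((2, 0, 4)))
        with pytest.raises(ValueError):
            channel_attention(np.full((1, 2, 2), np.nan))

    def test_permutation_equivariance_scalar_shared_mlp(self):
        m = _identity_channel_mlp(3)
        m.fc1.weight.data = 0.7 * np.eye(3)
        m.fc2.weight.data = 1.3 * np.eye(3)
        rng = np.random.default_rng(5)
        x = rng.standard_normal((3, 4, 4))
        perm = [2, 0, 1]
        s1, _ = channel_attention(x, module=m)
        s2, _ = channel_attention(x[perm], module=m)
        np.testing.assert_allclose(s2.weights, s1.weights[perm], atol=1e-12)


class TestSpatialAttention:
    def test_zero_input_zero_bias_gives_half(self):
        m = SpatialAttention(3, dtype=np.float64)
        m.conv.bias.data = np.zeros(1)
        state, _ = spatial_attention(np.zeros((2, 5, 5)), k_s=3, module=m)
        np.testing.assert_allclose(state.weights, 0.5)

    def test_channel_constant_pooling_identity(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((6, 6))
        x = np.repeat(base[None], 4, axis=0)
        state, _ = spatial_attention(x, k_s=3)
        np.testing.assert_array_equal(state.pooled_avg[0], state.pooled_max[0])
        np.testing.assert_allclose(state.pooled_avg[0], base, atol=1e-12)

    def test_rejects_even_kernel(self):
        with pytest.raises(ValueError):
            SpatialAttention(4)

    def test_matches_pixel_loop_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 6, 6))
        m = SpatialAttention(3, rng=np.random.default_rng(11), dtype=np.float64)
        state, gated = spatial_attention(x, k_s=3, module=m)
        w = m.conv.weight.data[0]  # (2,3,3)
        b = m.conv.bias.data[0]
        pooled = np.stack([x.mean(axis=0), x.max(axis=0)])
        padded = np.pad(pooled, ((0, 0), (1, 1), (1, 1)))
        expected = np.empty((6, 6))
        for i in range(6):
            for j in range(6):
                expected[i, j] = _sigmoid((padded[:, i : i + 3, j : j + 3] * w).sum() + b)
        np.testing.assert_allclose(state.weights[0], expected, atol=1e-6)
        np.testing.assert_allclose(gated, x * expected[None], atol=1e-6)

    def test_translation_equivariance_in_interior(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 16, 16))
        m = SpatialAttention(3, rng=np.random.default_rng(4), dtype=np.float64)
        s1, _ = spatial_attention(x, k_s=3, module=m)
        shifted = np.roll(x, (3, 2), axis=(1, 2))
        s2, _ = spatial_attention(shifted, k_s=3, module=m)
        rolled = np.roll(s1.weights, (3, 2), axis=(1, 2))
        margin = 5
        np.testing.assert_allclose(
            s2.weights[0, margin:-margin, margin:-margin],
            rolled[0, margin:-margin, margin:-margin], atol=1e-10)


class TestFusion:
    def _zero_bias_module(self, c, seed=0):
        m = AttentionFusion(c, ratio=1, kernel_size=3, rng=np.random.default_rng(seed),
                            dtype=np.float64)
        return m

    def test_all_zero_inputs_zero_biases_give_half(self):
        m = self._zero_bias_module(2)
        for sub in (m.ca_f, m.ca_g):
            sub.fc1.bias.data[:] = 0
            sub.fc2.bias.data[:] = 0
            sub.fc1.weight.data[:] = np.eye(2)
            sub.fc2.weight.data[:] = np.eye(2)
        for sub in (m.sa_f, m.sa_g):
            sub.conv.bias.data[:] = 0
        m.fuse.bias.data[:] = 0
        amap = csfag_attention_fusion(np.zeros((2, 4, 4)), np.zeros((2, 4, 4)), module=m)
        np.testing.assert_allclose(amap.values, 0.5)

    def test_open_interval_range(self):
        rng = np.random.default_rng(9)
        f = rng.standard_normal((3, 8, 8)) * 5
        g = rng.standard_normal((3, 8, 8)) * 5
        amap = csfag_attention_fusion(f, g, rng=np.random.default_rng(1))
        assert amap.values.min() > 0.0
        assert amap.values.max() < 1.0
        assert amap.values.shape == (1, 8, 8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            csfag_attention_fusion(np.zeros((2, 4, 4)), np.zeros((2, 5, 4)))

    def test_matches_composed_oracle(self):
        rng = np.random.default_rng(2)
        f = rng.standard_normal((2, 8, 8))
        g = rng.standard_normal((2, 8, 8))
        m = AttentionFusion(2, ratio=1, kernel_size=3, rng=np.random.default_rng(5),
                            dtype=np.float64)
        amap = csfag_attention_fusion(f, g, module=m)

        def branch(x, ca, sa):
            _, after_ca = channel_attention(x, module=ca)
            _, after_sa = spatial_attention(after_ca, k_s=3, module=sa)
            return after_sa.mean(axis=0)

        a0 = branch(f, m.ca_f, m.sa_f) + branch(g, m.ca_g, m.sa_g)
        a1 = np.maximum(a0, 0.0)
        w, b = m.fuse.weight.data[0, 0], m.fuse.bias.data[0]
        padded = np.pad(a1, 1)
        a2 = np.empty_like(a1)
        for i in range(8):
            for j in range(8):
                a2[i, j] = (padded[i : i + 3, j : j + 3] * w).sum() + b
        np.testing.assert_allclose(amap.pre_sum[0], a0, atol=1e-6)
        np.testing.assert_allclose(amap.values[0], _sigmoid(a2), atol=1e-6)


def test_gating_never_amplifies():
    rng = np.random.default_rng(8)
    x = rng.standard_normal((4, 7, 7)) * 3
    _, gated_c = channel_attention(x, rho=2, rng=np.random.default_rng(0))
    _, gated_s = spatial_attention(x, k_s=3, rng=np.random.default_rng(0))
    assert np.all(np.abs(gated_c) <= np.abs(x) + 1e-12)
    assert np.all(np.abs(gated_s) <= np.abs(x) + 1e-12)
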