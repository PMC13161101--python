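"""Convolutional building blocks: algebraic identities, oracle equivalences
and shape contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafdx import autograd as ag
from leafdx import nn
from leafdx.autograd import Tensor
from leafdx.primitives import (AugmentedConv2d, DepthwiseSeparable, GhostModule,
                               PushPull2d, SPConv, ShapeConv2d, channel_shuffle,
                               channel_shuffle_indices, patch_base, patch_shape)


class TestShapeConv:
    def test_base_plus_shape_reconstructs_patch_exactly(self, rng):
        """The base/shape decomposition is an algebraic identity; in float64
        the round trip is exact to one unit in the last place."""
        patch = rng.integers(-50, 50, size=(4, 3, 3)).astype(np.float64)
        np.testing.assert_allclose(patch_base(patch) + patch_shape(patch), patch,
                                   rtol=1e-15, atol=0)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_reconstruction_identity_property(self, seed):
        patch = np.random.default_rng(seed).standard_normal((2, 5, 5))
        np.testing.assert_allclose(patch_base(patch) + patch_shape(patch), patch,
                                   rtol=0, atol=1e-12)

    def test_unit_weights_reduce_to_vanilla_convolution(self, rng):
        """w_base = 1, w_shape = identity must reproduce plain convolution."""
        layer = ShapeConv2d(4, 3, 3)
        x = Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32))
        out = layer(x).data
        vanilla = ag.conv2d(x, layer.kernel, padding=1).data
        assert np.abs(out - vanilla).max() < 1e-5

    def test_constant_input_invariant_to_shape_weights(self, rng):
        """A constant patch has zero shape component, so w_shape is inert.
        Checked on interior positions, whose sliding patches are constant
        (border patches include zero padding and are not)."""
        layer = ShapeConv2d(2, 3, 3)
        x = Tensor(np.full((1, 2, 6, 6), 1.7, np.float32))
        before = layer(x).data.copy()
        layer.w_shape.data = rng.standard_normal(layer.w_shape.shape).astype(np.float32)
        after = layer(x).data
        np.testing.assert_allclose(after[:, :, 1:-1, 1:-1], before[:, :, 1:-1, 1:-1],
                                   atol=1e-4)

    def test_modulated_weights_match_direct_patch_oracle(self, rng):
        """With arbitrary w_base/w_shape the folded kernel must agree with
        explicitly modulating every sliding patch."""
        layer = ShapeConv2d(2, 2, 3)
        layer.w_base.data = rng.uniform(0.5, 1.5, 2).astype(np.float32)
        layer.w_shape.data = (np.eye(9) + 0.1 * rng.standard_normal((9, 9))
                              ).astype(np.float32)
        x = rng.standard_normal((1, 2, 5, 5)).astype(np.float32)
        out = layer(Tensor(x)).data

        xp = np.pad(x[0], ((0, 0), (1, 1), (1, 1)))
        k = layer.kernel.data
        want = np.zeros_like(out)
        for i in range(5):
            for j in range(5):
                patch = xp[:, i:i + 3, j:j + 3]                      # (C, 3, 3)
                pb = patch.mean(axis=(1, 2), keepdims=True)
                ps = (patch - pb).reshape(2, 9)
                mod = (layer.w_base.data[:, None, None] * pb
                       + (ps @ layer.w_shape.data.T).reshape(2, 3, 3))
                want[0, :, i, j] = (k * mod[None]).sum(axis=(1, 2, 3))
        np.testing.assert_allclose(out, want, atol=1e-4)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            ShapeConv2d(2, 2, 4)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ShapeConv2d(3, 2, 3)(Tensor(np.zeros((1, 4, 5, 5), np.float32)))


class TestAugmentedConv:
    def test_output_shape_contract(self, rng):
        layer = AugmentedConv2d(16, 32, attn_channels=8, heads=2)
        out = layer(Tensor(rng.standard_normal((1, 16, 7, 7)).astype(np.float32)))
        assert out.shape == (1, 32, 7, 7)

    def test_attention_rows_sum_to_one(self, rng):
        layer = AugmentedConv2d(8, 16, attn_channels=8, heads=2)
        x = Tensor(rng.standard_normal((2, 8, 5, 5)).astype(np.float32))
        _, attn = layer.attention(x)
        np.testing.assert_allclose(attn.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_position_reduces_to_value_projection(self, rng):
        """With one spatial position the softmax is trivially 1."""
        layer = AugmentedConv2d(6, 12, attn_channels=4, heads=2)
        x = Tensor(rng.standard_normal((1, 6, 1, 1)).astype(np.float32))
        out, _ = layer.attention(x)
        v = layer.qkv(x).data[:, 8:]                  # the value block
        np.testing.assert_allclose(out.data, v, atol=1e-6)

    @pytest.mark.parametrize("dv,heads", [(32, 4), (16, 3)])
    def test_invalid_specs_rejected(self, dv, heads):
        with pytest.raises(ValueError):
            AugmentedConv2d(8, 32, attn_channels=dv, heads=heads)


class TestGhostModule:
    def test_channel_arithmetic(self, rng):
        m = GhostModule(16, 64, ratio=2).eval()
        out = m(Tensor(rng.standard_normal((1, 16, 6, 6)).astype(np.float32)))
        assert out.shape == (1, 64, 6, 6)
        primary = m.primary(Tensor(rng.standard_normal((1, 16, 6, 6)).astype(np.float32)))
        assert primary.shape[1] == 32

    def test_ratio_one_is_primary_only(self, rng):
        m = GhostModule(8, 8, ratio=1).eval()
        x = Tensor(rng.standard_normal((1, 8, 5, 5)).astype(np.float32))
        np.testing.assert_array_equal(m(x).data, m.primary(x).data)

    def test_indivisible_ratio_rejected(self):
        with pytest.raises(ValueError):
            GhostModule(8, 10, ratio=4)


class TestSPConv:
    def test_split_arithmetic_and_shape(self, rng):
        m = SPConv(64, 64, split_ratio=0.5).eval()
        assert (m.rep, m.red) == (32, 32)
        out = m(Tensor(rng.standard_normal((2, 64, 14, 14)).astype(np.float32)))
        assert out.shape == (2, 64, 14, 14)
        assert np.isfinite(out.data).all()

    def test_full_ratio_drops_pointwise_path(self):
        m = SPConv(8, 8, split_ratio=1.0)
        assert m.red == 0
        assert not hasattr(m, "conv_red")

    @pytest.mark.parametrize("ratio", [0.0, 1.5])
    def test_invalid_ratio_rejected(self, ratio):
        with pytest.raises(ValueError):
            SPConv(8, 8, split_ratio=ratio)


class TestPushPull:
    def test_zero_input_zero_output(self):
        m = PushPull2d(3, 4, 5)
        out = m(Tensor(np.zeros((1, 3, 8, 8), np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_alpha_zero_is_rectified_push(self, rng):
        m = PushPull2d(3, 4, 3, alpha=0.0)
        x = Tensor(rng.standard_normal((1, 3, 6, 6)).astype(np.float32))
        np.testing.assert_allclose(m(x).data, np.maximum(m.conv(x).data, 0), atol=1e-6)

    @given(st.floats(0.0, 4.0), st.floats(0.0, 4.0))
    @settings(max_examples=20, deadline=None)
    def test_response_monotone_nonincreasing_in_alpha(self, a1, a2):
        lo, hi = sorted((a1, a2))
        nn.manual_seed(0)
        m = PushPull2d(2, 3, 3, alpha=lo)
        x = Tensor(np.random.default_rng(7).standard_normal((1, 2, 5, 5)).astype(np.float32))
        out_lo = m(x).data
        m.alpha = hi
        out_hi = m(x).data
        assert (out_hi <= out_lo + 1e-6).all()

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            PushPull2d(3, 3, 3, alpha=-0.1)


class TestDepthwiseSeparable:
    def test_parameter_count(self):
        m = DepthwiseSeparable(32, 64, 3)
        assert m.num_parameters() == 32 * 9 + 32 * 64 == 2336

    def test_identity_configuration(self):
        m = DepthwiseSeparable(3, 3, 1)
        m.depthwise.weight.data = np.ones((3, 1, 1, 1), np.float32)
        m.pointwise.weight.data = np.eye(3, dtype=np.float32).reshape(3, 3, 1, 1)
        x = np.random.default_rng(0).standard_normal((1, 3, 4, 4)).astype(np.float32)
        np.testing.assert_allclose(m(Tensor(x)).data, x, atol=1e-6)

    def test_shape_preserved(self, rng):
        out = DepthwiseSeparable(8, 16, 5)(
            Tensor(rng.standard_normal((2, 8, 9, 9)).astype(np.float32)))
        assert out.shape == (2, 16, 9, 9)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            DepthwiseSeparable(4, 4, 2)


class TestChannelShuffle:
    def test_six_channels_two_groups_permutation(self):
        x = np.arange(6, dtype=np.float32).reshape(1, 6, 1, 1)
        out = channel_shuffle(Tensor(x), 2).data.reshape(-1)
        np.testing.assert_array_equal(out, [0, 3, 1, 4, 2, 5])

    def test_one_group_is_identity(self, rng):
        x = Tensor(rng.standard_normal((2, 8, 3, 3)).astype(np.float32))
        np.testing.assert_array_equal(channel_shuffle(x, 1).data, x.data)

    @given(st.sampled_from([(4, 2), (6, 3), (12, 4), (12, 3), (8, 8)]))
    @settings(max_examples=10, deadline=None)
    def test_shuffle_bijective_and_invertible(self, cg):
        c, g = cg
        perm = channel_shuffle_indices(c, g)
        assert sorted(perm) == list(range(c))                 # bijection
        np.testing.assert_array_equal(perm[channel_shuffle_indices(c, c // g)],
                                      np.arange(c))           # inverse

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError):
            channel_shuffle(Tensor(np.zeros((1, 6, 2, 2), np.float32)), 4)


@pytest.mark.parametrize("make,cin", [
    (lambda: ShapeConv2d(4, 6, 3), 4),
    (lambda: AugmentedConv2d(4, 8, attn_channels=4, heads=2), 4),
    (lambda: GhostModule(4, 8), 4),
    (lambda: SPConv(8, 8), 8),
    (lambda: PushPull2d(4, 6, 3), 4),
    (lambda: DepthwiseSeparable(4, 6, 3), 4),
], ids=["shape", "augmented", "ghost", "spconv", "pushpull", "dwsep"])
def test_forward_preserves_batch_and_is_finite(make, cin, rng):
    m = make()
    if hasattr(m, "eval"):
        m.eval()
    x = Tensor(rng.standard_normal((3, cin, 6, 6)).astype(np.float32))
    out = m(x)
    assert out.shape[0] == 3 and out.shape[2:] == (6, 6)
    assert np.isfinite(out.data).all()
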