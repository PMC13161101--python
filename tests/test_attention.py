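"""Attention operators against independently coded naive oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafdx import nn
from leafdx.attention import (ECA, LGA, MCA, SGE, SKConv, SPP, eca_kernel_size,
                              mca_squeeze)
from leafdx.autograd import Tensor


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestEcaKernelSize:
    @pytest.mark.parametrize("channels,expected", [(64, 3), (256, 5), (2, 1)])
    def test_adaptive_mapping(self, channels, expected):
        assert eca_kernel_size(channels, gamma=2, b=1) == expected

    def test_always_odd_and_nondecreasing(self):
        ks = [eca_kernel_size(c) for c in range(1, 2049)]
        assert all(k % 2 == 1 and k >= 1 for k in ks)
        assert all(a <= b for a, b in zip(ks, ks[1:]))

    def test_invalid_channels_rejected(self):
        with pytest.raises(ValueError):
            eca_kernel_size(0)


class TestECA:
    def test_zero_kernel_gives_half_gate(self, rng):
        m = ECA(8)
        m.weight.data[:] = 0.0
        x = Tensor(rng.standard_normal((1, 8, 5, 5)).astype(np.float32))
        np.testing.assert_allclose(m(x).data, 0.5 * x.data, atol=1e-6)

    def test_identical_channels_get_identical_weights(self):
        """Channels with identical content and identical neighborhoods get
        identical weights from the shared 1-D kernel (interior channels;
        the first/last k//2 see zero padding)."""
        m = ECA(8)
        one = np.random.default_rng(1).standard_normal((1, 1, 4, 4))
        x = Tensor(np.repeat(one, 8, axis=1).astype(np.float32))
        w = m.attention_weights(x).data
        half = m.kernel_size // 2
        interior = w[:, half:8 - half]
        np.testing.assert_allclose(interior - interior[:, :1], 0.0, atol=1e-6)

    def test_matches_neighborhood_sum_oracle(self, rng):
        """Explicit per-channel loop over the k-neighborhood of the pooled
        descriptor must reproduce the layer."""
        m = ECA(8)   # k = 3 for 8 channels
        x = rng.standard_normal((1, 8, 5, 5)).astype(np.float32)
        out = m(Tensor(x)).data

        y = x.mean(axis=(2, 3))[0]                       # GAP descriptor
        k = m.kernel_size
        half = k // 2
        kernel = m.weight.data.reshape(k)
        want = np.empty_like(out)
        for i in range(8):
            acc = 0.0
            for j in range(k):                           # neighborhood sum
                src = i + j - half
                if 0 <= src < 8:
                    acc += kernel[j] * y[src]
            want[0, i] = sigmoid(acc) * x[0, i]
        np.testing.assert_allclose(out, want, atol=1e-5)

    def test_gates_strictly_inside_unit_interval(self, rng):
        m = ECA(16)
        w = m.attention_weights(
            Tensor(rng.standard_normal((2, 16, 4, 4)).astype(np.float32))).data
        assert ((w > 0) & (w < 1)).all()

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ECA(8)(Tensor(np.zeros((1, 4, 3, 3), np.float32)))


class TestLGA:
    def test_single_group_is_whole_tensor_attention(self, rng):
        """With one group every channel shares a single spatial gate
        computed from the whole tensor's channel mean."""
        m1 = LGA(8, groups=1)
        x = Tensor(rng.standard_normal((1, 8, 6, 6)).astype(np.float32))
        out = m1(x).data
        desc = Tensor(x.data.mean(axis=1, keepdims=True))
        gate = sigmoid(m1.gate(desc).data)
        np.testing.assert_allclose(out, x.data * gate, atol=1e-6)

    def test_gating_bounds_output(self, rng):
        m = LGA(8, groups=4)
        x = Tensor(rng.standard_normal((2, 8, 5, 5)).astype(np.float32))
        assert (np.abs(m(x).data) <= np.abs(x.data) + 1e-7).all()

    def test_identical_halves_get_identical_gates(self, rng):
        """Shared gate weights make symmetric inputs gate symmetrically."""
        m = LGA(8, groups=2)
        half = rng.standard_normal((1, 4, 5, 5)).astype(np.float32)
        x = Tensor(np.concatenate([half, half], axis=1))
        out = m(x).data
        np.testing.assert_allclose(out[:, :4], out[:, 4:], atol=1e-6)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError):
            LGA(6, groups=4)


class TestSGE:
    def test_constant_input_gates_at_half(self):
        m = SGE(8, groups=2)
        x = Tensor(np.full((1, 8, 4, 4), 2.5, np.float32))
        np.testing.assert_allclose(m(x).data, 0.5 * x.data, atol=1e-5)

    def test_shape_and_gate_bounds(self, rng):
        m = SGE(8, groups=4)
        x = Tensor(rng.standard_normal((2, 8, 6, 6)).astype(np.float32))
        out = m(x)
        assert out.shape == x.shape
        assert (np.abs(out.data) <= np.abs(x.data) + 1e-7).all()

    def test_scale_invariance_of_normalized_similarity(self, rng):
        """Doubling the input leaves the normalized similarity field — and
        hence the gates — unchanged; recomputed directly."""
        m = SGE(4, groups=2)
        x = rng.standard_normal((1, 4, 5, 5)).astype(np.float32)

        def gates(arr):
            grouped = arr.reshape(1, 2, 2, 5, 5)
            gvec = grouped.mean(axis=(3, 4), keepdims=True)
            sim = (grouped * gvec).sum(axis=2)
            cen = sim - sim.mean(axis=(2, 3), keepdims=True)
            std = np.sqrt((cen ** 2).mean(axis=(2, 3), keepdims=True) + m.eps)
            return sigmoid(cen / std)

        np.testing.assert_allclose(gates(x), gates(2 * x), atol=5e-4)
        # hence the module is homogeneous: f(2x) = 2 f(x) up to the eps guard
        np.testing.assert_allclose(m(Tensor(2 * x)).data, 2 * m(Tensor(x)).data,
                                   atol=5e-3)


class TestSKConv:
    def test_branch_weights_sum_to_one(self, rng):
        m = SKConv(8, 16)
        x = Tensor(rng.standard_normal((2, 8, 6, 6)).astype(np.float32))
        outs = [b(x) for b in m.branches]
        w = m.branch_weights(outs).data
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_branches_pass_through(self, rng):
        """A convex combination of equal points is that point."""
        m = SKConv(4, 8).eval()
        x = Tensor(rng.standard_normal((1, 4, 5, 5)).astype(np.float32))
        b0 = m.branches[0]
        out0 = b0(x)
        w = m.branch_weights([out0, out0]).data
        mixed = out0.data * w[:, 0, :, None, None] + out0.data * w[:, 1, :, None, None]
        np.testing.assert_allclose(mixed, out0.data, atol=1e-5)

    def test_matches_explicit_mixture_oracle(self, rng):
        m = SKConv(16, 16).eval()
        x = Tensor(rng.standard_normal((1, 16, 8, 8)).astype(np.float32))
        out = m(x).data
        outs = [b(x) for b in m.branches]
        fused = outs[0].data + outs[1].data
        s = fused.mean(axis=(2, 3))
        z = np.maximum(s @ m.reduce.weight.data.T + m.reduce.bias.data, 0)
        logits = (z @ m.expand.weight.data.T + m.expand.bias.data).reshape(1, 2, 16)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        w = e / e.sum(axis=1, keepdims=True)
        want = (outs[0].data * w[:, 0, :, None, None]
                + outs[1].data * w[:, 1, :, None, None])
        np.testing.assert_allclose(out, want, atol=1e-5)

    def test_single_branch_rejected(self):
        with pytest.raises(ValueError):
            SKConv(8, 8, kernels=(3,))


class TestMCASqueeze:
    def test_constant_input_descriptor(self):
        x = Tensor(np.full((1, 4, 3, 3), 2.0, np.float32))
        desc = mca_squeeze(x, blend=0.5).data
        np.testing.assert_allclose(desc, 0.5 * 2.0, atol=1e-3)

    def test_pure_average_at_blend_one(self, rng):
        x = rng.standard_normal((2, 4, 3, 3)).astype(np.float32)
        np.testing.assert_allclose(mca_squeeze(Tensor(x), 1.0).data,
                                   x.mean(axis=(2, 3)), atol=1e-6)

    def test_matches_direct_mean_std(self, rng):
        x = rng.standard_normal((1, 4, 3, 3)).astype(np.float32)
        want = 0.5 * x.mean(axis=(2, 3)) + 0.5 * np.sqrt(x.var(axis=(2, 3)) + 1e-8)
        np.testing.assert_allclose(mca_squeeze(Tensor(x), 0.5).data, want, atol=1e-6)

    def test_invalid_blend_rejected(self):
        with pytest.raises(ValueError):
            mca_squeeze(Tensor(np.zeros((1, 2, 2, 2), np.float32)), 1.5)


class TestMCA:
    @staticmethod
    def _oracle(m: MCA, x: np.ndarray) -> np.ndarray:
        """Loop-based recomputation of the three-branch attention."""
        perms = {"channel": (0, 1, 2, 3), "height": (0, 2, 1, 3), "width": (0, 3, 2, 1)}
        branches = []
        for name, perm in perms.items():
            view = x.transpose(perm)
            mu = view.mean(axis=(2, 3))
            std = np.sqrt(view.var(axis=(2, 3)) + 1e-8)
            desc = m.blend * mu + (1 - m.blend) * std
            kernel = getattr(m, f"w_{name}").data.reshape(-1)
            k = len(kernel)
            half = k // 2
            d = desc.shape[1]
            gate = np.empty_like(desc)
            for n in range(desc.shape[0]):
                for i in range(d):
                    acc = 0.0
                    for j in range(k):
                        src = i + j - half
                        if 0 <= src < d:
                            acc += kernel[j] * desc[n, src]
                    gate[n, i] = sigmoid(acc)
            refined = view * gate[:, :, None, None]
            branches.append(refined.transpose(perm))
        return (branches[0] + branches[1] + branches[2]) / 3.0

    def test_zero_excitation_halves_input(self, rng):
        m = MCA(4, 6, 5)
        for name in ("channel", "height", "width"):
            getattr(m, f"w_{name}").data[:] = 0.0
        x = Tensor(rng.standard_normal((2, 4, 6, 5)).astype(np.float32))
        np.testing.assert_allclose(m(x).data, 0.5 * x.data, atol=1e-6)

    def test_matches_loop_oracle(self, rng):
        m = MCA(4, 6, 5)
        x = rng.standard_normal((2, 4, 6, 5)).astype(np.float32)
        np.testing.assert_allclose(m(Tensor(x)).data, self._oracle(m, x), atol=1e-5)

    def test_output_is_exact_mean_of_branches(self, rng):
        m = MCA(4, 4, 4)
        x = Tensor(rng.standard_normal((1, 4, 4, 4)).astype(np.float32))
        fc = m._branch(x, "channel").data
        fh = m._branch(x, "height").data
        fw = m._branch(x, "width").data
        np.testing.assert_array_equal(m(x).data,
                                      ((fc + fh + fw) * np.float32(1.0 / 3.0)))

    def test_rank_checked(self):
        with pytest.raises(ValueError):
            MCA(4, 4, 4)(Tensor(np.zeros((4, 4, 4), np.float32)))


class TestSPP:
    def test_fixed_length_arithmetic(self, rng):
        m = SPP((1, 2, 4))
        x = Tensor(rng.standard_normal((1, 32, 13, 13)).astype(np.float32))
        out = m(x)
        assert out.shape == (1, 32 * 21) == (1, 672)
        out2 = m(Tensor(rng.standard_normal((1, 32, 20, 20)).astype(np.float32)))
        assert out2.shape == out.shape

    def test_level_one_is_global_max(self, rng):
        x = rng.standard_normal((2, 4, 9, 9)).astype(np.float32)
        out = SPP((1, 2))(Tensor(x)).data
        np.testing.assert_allclose(out[:, :4], x.max(axis=(2, 3)), atol=1e-6)

    @pytest.mark.parametrize("levels", [(0, 2), (2, 2), (4, 2)])
    def test_bad_levels_rejected(self, levels):
        with pytest.raises(ValueError):
            SPP(levels)

    def test_undersized_input_rejected(self):
        with pytest.raises(ValueError):
            SPP((1, 2, 4))(Tensor(np.zeros((1, 2, 3, 3), np.float32)))


@given(st.integers(0, 10 ** 6))
@settings(max_examples=15, deadline=None)
def test_all_gates_shape_preserving_and_bounded(seed):
    """Every attention operator preserves shape and never amplifies
    magnitudes (its gates lie in (0,1))."""
    rng = np.random.default_rng(seed)
    x = Tensor(rng.standard_normal((1, 8, 6, 6)).astype(np.float32))
    nn.manual_seed(seed % 1000)
    for m in (ECA(8), LGA(8, 2), SGE(8, 2)):
        out = m(x)
        assert out.shape == x.shape
        assert (np.abs(out.data) <= np.abs(x.data) + 1e-7).all()
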