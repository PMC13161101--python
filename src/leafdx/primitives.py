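"""Convolutional building blocks used by both feature-extraction tracks.

The blocks here are the low-level currency of the network:

* :class:`ShapeConv2d` — shape-aware convolution that decomposes every
  sliding patch into a base component (its spatial mean) and a shape
  component (deviation from the mean), re-weights the two with learnable
  coefficients, and convolves the recombined patch.
* :class:`AugmentedConv2d` — convolution run in parallel with multi-head
  self-attention over all spatial positions; the two branch outputs are
  concatenated channel-wise.
* :class:`GhostModule` — a primary convolution producing intrinsic maps
  plus a cheap depthwise convolution generating the remaining "ghost" maps.
* :class:`SPConv` — split convolution: a representative channel subset gets
  a 3x3 path, the redundant remainder a 1x1 path; paths are fused by
  pooled softmax weights with shuffle, batch norm and a residual shortcut.
* :class:`PushPull2d` — rectified push convolution inhibited by the
  rectified response of the negated (pull) kernel.
* :class:`DepthwiseSeparable` — depthwise k x k filtering followed by a
  pointwise 1x1 channel mixer, bias-free.
* :func:`channel_shuffle` — the grouped-channel interleaving permutation.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor


def _odd(k: int, name: str = "kernel") -> int:
    k = int(k)
    if k < 1 or k % 2 == 0:
        raise ValueError(f"{name} size must be odd and >= 1, got {k}")
    return k


# -- shape-aware convolution -------------------------------------------------

def patch_base(patch: np.ndarray, axis=(-2, -1)) -> np.ndarray:
    """Base component of a patch: its mean over the spatial kernel window."""
    return patch.mean(axis=axis, keepdims=True)


def patch_shape(patch: np.ndarray, axis=(-2, -1)) -> np.ndarray:
    """Shape component of a patch: deviation from the spatial mean."""
    return patch - patch.mean(axis=axis, keepdims=True)


class ShapeConv2d(nn.Module):
    """Shape-aware convolution.

    Every K_h x K_w patch P is split into a base component P_B = m(P)
    (mean over the kernel window, per channel) and a shape component
    P_S = P - m(P), so P_B + P_S reconstructs P exactly.  The base is
    re-weighted by a per-channel scalar ``w_base`` (broadcast product) and
    the shape coefficients by a learnable (K·K) x (K·K) linear transform
    ``w_shape``; the modulated patch is then convolved with the kernel.

    Because both components are linear in P, the whole operation folds into
    an equivalent dense convolution whose kernel is computed from
    (kernel, w_base, w_shape) on every forward pass, which is how it is
    evaluated here.  With ``w_base = 1`` and ``w_shape = I`` the layer is
    exactly a vanilla convolution.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 bias: bool = False):
        super().__init__()
        k = _odd(kernel_size)
        self.in_channels, self.out_channels, self.kernel_size = in_channels, out_channels, k
        n = k * k
        fan_in = in_channels * n
        self.kernel = nn.kaiming_uniform((out_channels, in_channels, k, k), fan_in)
        self.w_base = nn.Parameter(np.ones(in_channels, dtype=np.float32))
        self.w_shape = nn.Parameter(np.eye(n, dtype=np.float32))
        self.bias = nn.Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def effective_kernel(self) -> Tensor:
        """Fold (kernel, w_base, w_shape) into one dense convolution kernel.

        For a patch p (flattened to length n) the modulated patch is
        M = w_base * mean(p) + w_shape @ (p - mean(p)); substituting into
        the convolution sum gives an equivalent kernel
        K_eff[o,c,:] = K[o,c,:] @ (w_shape - rowmean) + w_base[c] * sum(K[o,c,:]) / n.
        """
        co, ci, k, _ = self.kernel.shape
        n = k * k
        k3 = self.kernel.reshape(co, ci, n)
        centered = self.w_shape - self.w_shape.sum(axis=1, keepdims=True) * (1.0 / n)
        term1 = k3.matmul(centered)
        ksum = k3.sum(axis=2, keepdims=True)
        term2 = ksum * (self.w_base * (1.0 / n)).reshape(1, ci, 1)
        return (term1 + term2).reshape(co, ci, k, k)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}")
        pad = (self.kernel_size - 1) // 2
        return ag.conv2d(x, self.effective_kernel(), self.bias, padding=pad)


# -- attention-augmented convolution -----------------------------------------

class AugmentedConv2d(nn.Module):
    """Convolution merged with parallel multi-head self-attention.

    The convolution branch produces ``out_channels - attn_channels`` maps;
    the attention branch projects the input to queries/keys/values with 1x1
    convolutions, attends over all H*W positions with ``heads`` heads, and
    contributes the remaining ``attn_channels`` maps.  Outputs are
    concatenated along channels; spatial size is preserved.  Positional
    encodings are not used.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 attn_channels: int | None = None, heads: int = 4,
                 kernel_size: int = 3):
        super().__init__()
        if attn_channels is None:
            attn_channels = out_channels // 4
        if attn_channels >= out_channels:
            raise ValueError("attn_channels must be smaller than out_channels")
        if attn_channels % heads != 0:
            raise ValueError("attn_channels must be divisible by the head count")
        k = _odd(kernel_size)
        self.out_channels, self.attn_channels, self.heads = out_channels, attn_channels, heads
        self.conv = nn.Conv2d(in_channels, out_channels - attn_channels, k,
                              padding=(k - 1) // 2, bias=False)
        # queries/keys share the value width; one fused 1x1 projection
        self.qkv = nn.Conv2d(in_channels, 3 * attn_channels, 1, bias=False)

    def attention(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Return (attention output, per-head attention weights)."""
        n, _, h, w = x.shape
        dv, nh = self.attn_channels, self.heads
        dh = dv // nh
        L = h * w
        qkv = self.qkv(x).reshape(n, 3, nh, dh, L)
        q, k, v = qkv[:, 0], qkv[:, 1], qkv[:, 2]          # each (n, nh, dh, L)
        logits = q.permute(0, 1, 3, 2).matmul(k) * (1.0 / np.sqrt(dh))
        attn = logits.softmax(axis=-1)                      # (n, nh, L, L)
        out = attn.matmul(v.permute(0, 1, 3, 2))            # (n, nh, L, dh)
        out = out.permute(0, 1, 3, 2).reshape(n, dv, h, w)
        return out, attn

    def forward(self, x: Tensor) -> Tensor:
        conv_out = self.conv(x)
        attn_out, _ = self.attention(x)
        return ag.concatenate([conv_out, attn_out], axis=1)


# -- ghost module ------------------------------------------------------------

class GhostModule(nn.Module):
    """Primary convolution plus cheap depthwise "ghost" maps.

    ``out_channels / ratio`` intrinsic maps come from the primary
    convolution; the remaining ``(ratio-1) * out_channels / ratio`` ghost
    maps are produced by a depthwise convolution over the intrinsic maps.
    ``ratio == 1`` degenerates to the primary convolution alone.
    """

    def __init__(self, in_channels: int, out_channels: int, ratio: int = 2,
                 primary_kernel: int = 1, cheap_kernel: int = 3):
        super().__init__()
        if ratio < 1 or out_channels % ratio != 0:
            raise ValueError("out_channels must be divisible by ratio >= 1")
        pk, ck = _odd(primary_kernel), _odd(cheap_kernel)
        self.ratio = ratio
        intrinsic = out_channels // ratio
        self.primary = nn.ConvBNAct(in_channels, intrinsic, pk, act="relu")
        if ratio > 1:
            self.cheap = nn.Sequential(
                nn.Conv2d(intrinsic, intrinsic * (ratio - 1), ck,
                          padding=(ck - 1) // 2, groups=intrinsic, bias=False),
                nn.BatchNorm2d(intrinsic * (ratio - 1)),
                nn.ReLU(),
            )

    def forward(self, x: Tensor) -> Tensor:
        primary = self.primary(x)
        if self.ratio == 1:
            return primary
        return ag.concatenate([primary, self.cheap(primary)], axis=1)


# -- split convolution -------------------------------------------------------

class SPConv(nn.Module):
    """Split convolution over representative vs redundant channels.

    The first ``round(split_ratio * in_channels)`` channels (representative)
    go through a 3x3 convolution, the remainder (redundant) through a 1x1
    convolution; both paths emit ``out_channels`` maps that are fused by a
    per-channel softmax over pooled path descriptors, channel-shuffled,
    batch-normalized and combined with a residual shortcut.
    """

    def __init__(self, in_channels: int, out_channels: int, split_ratio: float = 0.5):
        super().__init__()
        if not 0.0 < split_ratio <= 1.0:
            raise ValueError("split_ratio must lie in (0, 1]")
        rep = int(round(split_ratio * in_channels))
        if rep < 1:
            raise ValueError("representative channel count must be >= 1")
        self.rep = rep
        self.red = in_channels - rep
        self.conv_rep = nn.Conv2d(rep, out_channels, 3, padding=1, bias=False)
        if self.red > 0:
            self.conv_red = nn.Conv2d(self.red, out_channels, 1, bias=False)
        self.bn = nn.BatchNorm2d(out_channels)
        if in_channels != out_channels:
            self.shortcut = nn.Conv2d(in_channels, out_channels, 1, bias=False)
        else:
            self.shortcut = nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        rep_out = self.conv_rep(x[:, :self.rep])
        if self.red == 0:
            fused = rep_out
        else:
            red_out = self.conv_red(x[:, self.rep:])
            pooled = ag.stack([ag.global_avg_pool(rep_out),
                               ag.global_avg_pool(red_out)], axis=1)   # (n, 2, C)
            weights = pooled.softmax(axis=1)
            n, _, c = weights.shape
            w_rep = weights[:, 0].reshape(n, c, 1, 1)
            w_red = weights[:, 1].reshape(n, c, 1, 1)
            fused = rep_out * w_rep + red_out * w_red
        fused = channel_shuffle(fused, 2) if fused.shape[1] % 2 == 0 else fused
        return self.bn(fused) + self.shortcut(x)


# -- push-pull convolution ---------------------------------------------------

class PushPull2d(nn.Module):
    """Push-pull convolution: excitatory filter inhibited by its negation.

    response = relu(conv(x, k)) - alpha * relu(conv(x, -k)).  The pull
    kernel is the negated push kernel at the same size, so the response is
    pointwise non-increasing in the inhibition strength ``alpha``.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 5,
                 alpha: float = 1.0, stride: int = 1):
        super().__init__()
        if alpha < 0:
            raise ValueError("inhibition strength alpha must be non-negative")
        k = _odd(kernel_size)
        self.alpha = float(alpha)
        self.conv = nn.Conv2d(in_channels, out_channels, k, stride=stride,
                              padding=(k - 1) // 2, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        push = self.conv(x)           # bias-free, so conv(x, -k) == -push
        return push.relu() - self.alpha * (-push).relu()


# -- depthwise separable convolution -----------------------------------------

class DepthwiseSeparable(nn.Module):
    """Depthwise k x k convolution followed by a pointwise 1x1, bias-free.

    Parameter count is C_in * k^2 + C_in * C_out versus C_in * C_out * k^2
    for the dense equivalent.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1):
        super().__init__()
        k = _odd(kernel_size)
        self.depthwise = nn.Conv2d(in_channels, in_channels, k, stride=stride,
                                   padding=(k - 1) // 2, groups=in_channels, bias=False)
        self.pointwise = nn.Conv2d(in_channels, out_channels, 1, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


# -- channel shuffle ---------------------------------------------------------

def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Interleave channels across ``groups``: reshape(g, C/g) -> transpose -> flatten.

    A pure permutation of channel indices; shuffling with ``groups`` followed
    by shuffling with ``C // groups`` restores the original order.
    """
    n, c, h, w = x.shape
    if groups < 1 or c % groups != 0:
        raise ValueError(f"channel count {c} not divisible by groups {groups}")
    return (x.reshape(n, groups, c // groups, h, w)
             .permute(0, 2, 1, 3, 4)
             .reshape(n, c, h, w))


def channel_shuffle_indices(channels: int, groups: int) -> np.ndarray:
    """The channel permutation applied by :func:`channel_shuffle`."""
    if groups < 1 or channels % groups != 0:
        raise ValueError(f"channel count {channels} not divisible by groups {groups}")
    return np.arange(channels).reshape(groups, channels // groups).T.reshape(-1)
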