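"""Attention operators and the spatial-pyramid pooling aggregator.

* :class:`ECA` — efficient channel attention: per-channel weights from a
  1-D convolution over the globally average-pooled channel descriptor,
  without dimensionality reduction; the 1-D kernel size is derived from
  the channel count by :func:`eca_kernel_size`.
* :class:`LGA` — local group attention: channels split into groups, each
  gated by a shared spatial sigmoid map computed from the group's pooled
  descriptor.
* :class:`SGE` — spatial group-wise enhance: per-group similarity of each
  position's local vector with the group's global-average vector,
  normalized over space and sigmoid-gated.
* :class:`SKConv` — selective-kernel convolution: multi-kernel branches
  mixed by per-channel softmax weights computed from the fused descriptor.
* :class:`MCA` — multidimensional collaborative attention over the
  channel, height and width axes, each branch squeezing with a blend of
  average and standard-deviation pooling and exciting with a local 1-D
  convolution gate; outputs averaged.
* :class:`SPP` — multi-level adaptive max pooling flattened to a
  fixed-length vector.
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor


def eca_kernel_size(channels: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive 1-D kernel size for channel attention.

    k = floor((log2(C) + b) / gamma), bumped to the next odd number and
    floored at 1, so it grows (non-strictly) with the channel count.
    """
    if channels < 1:
        raise ValueError("channel count must be >= 1")
    k = int(math.floor((math.log2(channels) + b) / gamma))
    if k % 2 == 0:
        k += 1
    return max(k, 1)


def _conv1d_over_channels(y: Tensor, weight: Tensor) -> Tensor:
    """1-D convolution of a (N, C) descriptor with a length-k kernel, same-padded."""
    n, c = y.shape
    k = weight.shape[-1]
    return ag.conv2d(y.reshape(n, 1, 1, c), weight, padding=(0, (k - 1) // 2)).reshape(n, c)


class ECA(nn.Module):
    """Efficient channel attention (no dimensionality reduction)."""

    def __init__(self, channels: int, gamma: int = 2, b: int = 1):
        super().__init__()
        self.channels = channels
        k = eca_kernel_size(channels, gamma, b)
        self.kernel_size = k
        self.weight = nn.kaiming_uniform((1, 1, 1, k), k)

    def attention_weights(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        y = ag.global_avg_pool(x)                       # (n, C)
        return _conv1d_over_channels(y, self.weight).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        w = self.attention_weights(x)
        n, c = w.shape
        return x * w.reshape(n, c, 1, 1)


class LGA(nn.Module):
    """Local group attention: grouped multiplicative spatial gating.

    Channels are split into ``groups``; each group's pooled (channel-mean)
    descriptor map passes through a small shared convolution and a sigmoid
    to give a spatial gate in (0,1)^{HxW}, applied multiplicatively.
    """

    def __init__(self, channels: int, groups: int = 4, gate_kernel: int = 3):
        super().__init__()
        if channels % groups != 0:
            raise ValueError("channels must be divisible by the group count")
        if gate_kernel % 2 == 0:
            raise ValueError("gate kernel must be odd")
        self.channels, self.groups = channels, groups
        self.gate = nn.Conv2d(1, 1, gate_kernel, padding=(gate_kernel - 1) // 2)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        grouped = x.reshape(n, g, c // g, h, w)
        desc = grouped.mean(axis=2).reshape(n * g, 1, h, w)
        gates = self.gate(desc).sigmoid().reshape(n, g, 1, h, w)
        return (grouped * gates).reshape(n, c, h, w)


class SGE(nn.Module):
    """Spatial group-wise enhance.

    Per group, the similarity of each spatial position's local feature with
    the group's global-average vector is normalized to zero mean / unit
    variance over space (eps-guarded), affinely rescaled by a learnable
    per-group scale and shift, sigmoid-gated and applied multiplicatively.
    """

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        super().__init__()
        if channels % groups != 0:
            raise ValueError("channels must be divisible by the group count")
        self.channels, self.groups, self.eps = channels, groups, eps
        self.scale = nn.Parameter(np.ones((1, groups, 1, 1), dtype=np.float32))
        self.shift = nn.Parameter(np.zeros((1, groups, 1, 1), dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        grouped = x.reshape(n, g, c // g, h, w)
        global_vec = grouped.mean(axis=(3, 4), keepdims=True)
        sim = (grouped * global_vec).sum(axis=2)            # (n, g, h, w)
        mu = sim.mean(axis=(2, 3), keepdims=True)
        centered = sim - mu
        std = ((centered ** 2).mean(axis=(2, 3), keepdims=True) + self.eps).sqrt()
        gate = (centered / std * self.scale + self.shift).sigmoid()
        return (grouped * gate.reshape(n, g, 1, h, w)).reshape(n, c, h, w)


class SKConv(nn.Module):
    """Selective-kernel convolution with softmax branch attention.

    Two branches convolve the input at effective receptive fields 3x3 and
    5x5 (the latter as a dilated 3x3); the fused sum is pooled, reduced to
    ``max(out_channels // reduction, 4)`` units and expanded to per-branch,
    per-channel logits whose softmax (summing to 1 across branches) mixes
    the branch outputs.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 kernels: tuple[int, ...] = (3, 5), reduction: int = 8):
        super().__init__()
        if len(kernels) < 2:
            raise ValueError("selective kernel needs at least two branches")
        self.out_channels = out_channels
        self.branches = nn.Sequential(*[
            nn.ConvBNAct(in_channels, out_channels, 3,
                         dilation=(k - 1) // 2, act="relu")
            for k in kernels
        ])
        hidden = max(out_channels // reduction, 4)
        self.reduce = nn.Linear(out_channels, hidden)
        self.expand = nn.Linear(hidden, out_channels * len(kernels))

    def branch_weights(self, branch_outputs: list[Tensor]) -> Tensor:
        fused = branch_outputs[0]
        for b in branch_outputs[1:]:
            fused = fused + b
        s = ag.global_avg_pool(fused)
        z = self.reduce(s).relu()
        logits = self.expand(z).reshape(s.shape[0], len(branch_outputs), self.out_channels)
        return logits.softmax(axis=1)                      # (n, branches, C)

    def forward(self, x: Tensor) -> Tensor:
        outs = [branch(x) for branch in self.branches]
        weights = self.branch_weights(outs)
        n, _, c = weights.shape
        mixed = outs[0] * weights[:, 0].reshape(n, c, 1, 1)
        for i, o in enumerate(outs[1:], start=1):
            mixed = mixed + o * weights[:, i].reshape(n, c, 1, 1)
        return mixed


def mca_squeeze(view: Tensor, blend: float = 0.5, eps: float = 1e-8) -> Tensor:
    """Squeeze transformation of one attention branch.

    For a view with the attended axis in the channel slot, returns
    ``blend * mean + (1 - blend) * std`` over the two non-attended axes,
    one descriptor per attended unit, shape (N, D).  The standard
    deviation is eps-guarded.
    """
    if not 0.0 <= blend <= 1.0:
        raise ValueError("squeeze blend must lie in [0, 1]")
    mu = view.mean(axis=(2, 3))
    var = ((view - view.mean(axis=(2, 3), keepdims=True)) ** 2).mean(axis=(2, 3))
    std = (var + eps).sqrt()
    return mu * blend + std * (1.0 - blend)


class MCA(nn.Module):
    """Multidimensional collaborative attention over channel/height/width.

    Each branch permutes its attended axis into the channel slot, squeezes
    with :func:`mca_squeeze`, excites with an unshared local 1-D
    convolution (ECA-style) followed by a sigmoid gate, rescales the view,
    and permutes back; the output is the arithmetic mean of the three
    refined maps.  Input spatial/channel sizes are fixed at construction
    because each branch's 1-D kernel size depends on its axis length.
    """

    _perms = {"channel": (0, 1, 2, 3), "height": (0, 2, 1, 3), "width": (0, 3, 2, 1)}

    def __init__(self, channels: int, height: int, width: int, blend: float = 0.5):
        super().__init__()
        if not 0.0 <= blend <= 1.0:
            raise ValueError("squeeze blend must lie in [0, 1]")
        self.blend = blend
        self.dims = {"channel": channels, "height": height, "width": width}
        for name, d in self.dims.items():
            k = eca_kernel_size(d)
            setattr(self, f"w_{name}", nn.kaiming_uniform((1, 1, 1, k), k))

    def _branch(self, x: Tensor, name: str) -> Tensor:
        perm = self._perms[name]
        view = x.permute(perm)
        desc = mca_squeeze(view, self.blend)
        gate = _conv1d_over_channels(desc, getattr(self, f"w_{name}")).sigmoid()
        n, d = gate.shape
        refined = view * gate.reshape(n, d, 1, 1)
        return refined.permute(perm)   # all three perms are involutions

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4:
            raise ValueError("MCA expects a rank-4 feature map")
        fc = self._branch(x, "channel")
        fh = self._branch(x, "height")
        fw = self._branch(x, "width")
        return (fc + fh + fw) * (1.0 / 3.0)


class SPP(nn.Module):
    """Spatial pyramid pooling: multi-level adaptive max pooling.

    For each level l the map is max-pooled to l x l and flattened; the
    concatenation has fixed length C * sum(l^2) regardless of input H, W.
    """

    def __init__(self, levels: tuple[int, ...] = (1, 2, 4)):
        super().__init__()
        levels = tuple(int(l) for l in levels)
        if any(l < 1 for l in levels) or list(levels) != sorted(set(levels)):
            raise ValueError("levels must be positive and strictly increasing")
        self.levels = levels

    def output_length(self, channels: int) -> int:
        return channels * sum(l * l for l in self.levels)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if min(h, w) < max(self.levels):
            raise ValueError("spatial size smaller than the largest pyramid level")
        pieces = [ag.adaptive_max_pool2d(x, l).reshape(n, c * l * l) for l in self.levels]
        return ag.concatenate(pieces, axis=1)
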