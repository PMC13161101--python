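"""MobileNetV3-Large, re-implemented from its published architecture.

The feature stack is the standard inverted-residual / squeeze-excitation /
hard-swish design with output stride 32: a 224-pixel input yields a
960-channel 7x7 terminal feature map.  The standalone classifier
(960 -> 1280 -> num_classes) brings the 1000-class configuration to
5.48 M trainable parameters.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor

# (kernel, expanded, out, use_se, activation, stride) per inverted-residual block
_LARGE_CONFIG = [
    (3, 16, 16, False, "relu", 1),
    (3, 64, 24, False, "relu", 2),
    (3, 72, 24, False, "relu", 1),
    (5, 72, 40, True, "relu", 2),
    (5, 120, 40, True, "relu", 1),
    (5, 120, 40, True, "relu", 1),
    (3, 240, 80, False, "hardswish", 2),
    (3, 200, 80, False, "hardswish", 1),
    (3, 184, 80, False, "hardswish", 1),
    (3, 184, 80, False, "hardswish", 1),
    (3, 480, 112, True, "hardswish", 1),
    (3, 672, 112, True, "hardswish", 1),
    (5, 672, 160, True, "hardswish", 2),
    (5, 960, 160, True, "hardswish", 1),
    (5, 960, 160, True, "hardswish", 1),
]

FEATURE_CHANNELS = 960


def _make_divisible(v: float, divisor: int = 8) -> int:
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


class SqueezeExcite(nn.Module):
    """Channel gating from the pooled descriptor (reduce 4x, hard-sigmoid)."""

    def __init__(self, channels: int):
        super().__init__()
        squeeze = _make_divisible(channels // 4)
        self.fc1 = nn.Conv2d(channels, squeeze, 1)
        self.fc2 = nn.Conv2d(squeeze, channels, 1)
        self.hsig = nn.Hardsigmoid()

    def forward(self, x: Tensor) -> Tensor:
        n, c, _, _ = x.shape
        s = ag.global_avg_pool(x).reshape(n, c, 1, 1)
        s = self.hsig(self.fc2(self.fc1(s).relu()))
        return x * s


class InvertedResidual(nn.Module):
    def __init__(self, in_ch: int, kernel: int, expanded: int, out_ch: int,
                 use_se: bool, act: str, stride: int):
        super().__init__()
        self.use_residual = stride == 1 and in_ch == out_ch
        layers: list[nn.Module] = []
        if expanded != in_ch:
            layers.append(nn.ConvBNAct(in_ch, expanded, 1, act=act))
        layers.append(nn.ConvBNAct(expanded, expanded, kernel, stride=stride,
                                   groups=expanded, act=act))
        if use_se:
            layers.append(SqueezeExcite(expanded))
        layers.append(nn.ConvBNAct(expanded, out_ch, 1, act="none"))
        self.block = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        out = self.block(x)
        return out + x if self.use_residual else out


class MobileNetV3Features(nn.Module):
    """The convolutional feature stack (input 3 x H x W, output 960 x H/32 x W/32)."""

    def __init__(self):
        super().__init__()
        blocks: list[nn.Module] = [nn.ConvBNAct(3, 16, 3, stride=2, act="hardswish")]
        in_ch = 16
        for kernel, expanded, out_ch, use_se, act, stride in _LARGE_CONFIG:
            blocks.append(InvertedResidual(in_ch, kernel, expanded, out_ch,
                                           use_se, act, stride))
            in_ch = out_ch
        blocks.append(nn.ConvBNAct(in_ch, FEATURE_CHANNELS, 1, act="hardswish"))
        self.stack = nn.Sequential(*blocks)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] < 32 or x.shape[3] < 32:
            raise ValueError("input smaller than the output stride (32)")
        return self.stack(x)


class MobileNetV3(nn.Module):
    """Feature stack plus the standard pooled classifier head."""

    def __init__(self, num_classes: int = 1000, dropout: float = 0.2):
        super().__init__()
        self.features = MobileNetV3Features()
        self.fc1 = nn.Linear(FEATURE_CHANNELS, 1280)
        self.act = nn.Hardswish()
        self.dropout = nn.Dropout(dropout)
        self.fc2 = nn.Linear(1280, num_classes)

    def forward(self, x: Tensor) -> Tensor:
        f = ag.global_avg_pool(self.features(x))
        return self.fc2(self.dropout(self.act(self.fc1(f))))
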