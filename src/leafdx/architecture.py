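"""Dual-track network assembly and model accounting.

Track 1 passes the image through the MobileNetV3-Large feature stack and a
multi-convolutional shape-aware kernel (MCSK) block; track 2 is the
hierarchical shuffled group attention network (HSGAN).  Both tracks emit
feature maps of equal spatial size which the fusion head concatenates,
refines with multidimensional collaborative attention (MCA), aggregates
with spatial pyramid pooling (SPP) and classifies through a dropout +
dense + ReLU + dense stack.

Also here: the four ablation variants (backbone only, backbone + MCSK,
HSGAN only, full), trainable-parameter counting and MAC/FLOP accounting
over a traced forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autograd as ag
from . import nn
from .attention import ECA, LGA, MCA, SGE, SKConv, SPP
from .autograd import Tensor
from .mobilenetv3 import FEATURE_CHANNELS, MobileNetV3, MobileNetV3Features
from .primitives import (AugmentedConv2d, DepthwiseSeparable, GhostModule,
                         PushPull2d, SPConv, ShapeConv2d, channel_shuffle)

VARIANTS = ("backbone_only", "backbone_mcsk", "hsgan_only", "full")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``hsgan_channels`` must be strictly increasing: deeper hierarchical
    blocks carry larger channel dimensions.  ``input_size`` is the square
    resize target in pixels; both tracks reach spatial size
    ``input_size / 32`` (7x7 at 224), so ``input_size`` must be a multiple
    of 32 no smaller than 32 and large enough for the top SPP level.
    """

    num_classes: int = 10
    input_size: int = 224
    hsgan_channels: tuple[int, ...] = (32, 64, 128, 256)
    hsgan_stem_channels: int = 16
    mcsk_channels: int = 256
    fusion_dropout: float = 0.5
    head_hidden: int = 512
    spp_levels: tuple[int, ...] = (1, 2, 4)
    lga_groups: int = 4
    sge_groups: int = 8
    pretrained_backbone: bool = False

    def __post_init__(self):
        self.hsgan_channels = tuple(self.hsgan_channels)
        self.spp_levels = tuple(self.spp_levels)
        if self.num_classes < 2:
            raise ValueError("need at least two classes")
        if list(self.hsgan_channels) != sorted(set(self.hsgan_channels)):
            raise ValueError("hsgan_channels must be strictly increasing")
        if self.input_size < 32 or self.input_size % 32 != 0:
            raise ValueError("input_size must be a positive multiple of 32 "
                             "(both tracks downsample by 32)")
        if self.mcsk_channels % 2 != 0:
            raise ValueError("mcsk_channels must be even (two concatenated paths)")
        if self.pretrained_backbone:
            raise NotImplementedError(
                "published backbone weights are not bundled; initialize seeded instead")

    def to_dict(self) -> dict:
        return asdict(self)


def build_backbone(cfg: ModelConfig | None = None, num_classes: int | None = None):
    """The MobileNetV3-Large feature stack, or the full classifier when
    ``num_classes`` is given (the standalone ablation baseline)."""
    if num_classes is not None:
        return MobileNetV3(num_classes)
    return MobileNetV3Features()


class MCSKBlock(nn.Module):
    """Multi-convolutional shape-aware kernel block.

    Two parallel paths — shape convolution and attention-augmented
    convolution, each followed by a ghost module and a split convolution —
    are concatenated and fused through selective-kernel convolution and
    spatial group-wise enhancement.  Each path emits ``out_channels // 2``
    maps so the concatenation matches ``out_channels``.
    """

    def __init__(self, in_channels: int = FEATURE_CHANNELS, out_channels: int = 256,
                 sge_groups: int = 8):
        super().__init__()
        half = out_channels // 2
        # a quarter of the path width attends; head count adapts to narrow
        # desk-scale configurations (4 heads at full width)
        attn = max(half // 4, 1)
        heads = min(4, attn)
        attn += (-attn) % heads
        self.in_channels = in_channels
        self.shape_path = nn.Sequential(
            ShapeConv2d(in_channels, half, 3),
            nn.BatchNorm2d(half), nn.ReLU(),
            GhostModule(half, half, ratio=2),
            SPConv(half, half, split_ratio=0.5),
        )
        self.aug_path = nn.Sequential(
            AugmentedConv2d(in_channels, half, attn_channels=attn, heads=heads),
            nn.BatchNorm2d(half), nn.ReLU(),
            GhostModule(half, half, ratio=2),
            SPConv(half, half, split_ratio=0.5),
        )
        self.sk = SKConv(out_channels, out_channels)
        self.sge = SGE(out_channels, groups=sge_groups)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels from the backbone")
        merged = ag.concatenate([self.shape_path(x), self.aug_path(x)], axis=1)
        return self.sge(self.sk(merged))


class HierarchicalBlock(nn.Module):
    """One hierarchical dual-pipeline block of the HSGAN track.

    Pipeline A: pointwise convolution to ``width`` then a depthwise
    separable 3x3 (local features).  Pipeline B: a wider 5x5 convolution to
    ``width`` then local group attention (context).  Both pipelines see the
    same input (fan-out); their sum plus a projected residual is passed
    through a channel shuffle.  Optional 2x downsampling at block entry.
    """

    def __init__(self, in_channels: int, width: int, downsample: bool = True,
                 lga_groups: int = 4, shuffle_groups: int = 4):
        super().__init__()
        if width % lga_groups != 0:
            raise ValueError("width must be divisible by the LGA group count")
        self.downsample = downsample
        self.shuffle_groups = shuffle_groups
        self.pw = nn.ConvBNAct(in_channels, width, 1, act="relu")
        self.dw_sep = DepthwiseSeparable(width, width, 3)
        self.dw_bn = nn.BatchNorm2d(width)
        self.wide = nn.ConvBNAct(in_channels, width, 5, act="relu")
        self.lga = LGA(width, groups=lga_groups)
        self.proj = nn.ConvBNAct(in_channels, width, 1, act="none")

    def forward(self, x: Tensor) -> Tensor:
        if self.downsample:
            h, w = x.shape[2] // 2, x.shape[3] // 2
            x = ag.adaptive_avg_pool2d(x, (h, w))
        a = self.dw_bn(self.dw_sep(self.pw(x)))
        b = self.lga(self.wide(x))
        out = (a + b + self.proj(x)).relu()
        return channel_shuffle(out, self.shuffle_groups)


class HSGAN(nn.Module):
    """Hierarchical shuffled group attention network (track 2).

    Push-pull stem (stride 2) -> stacked hierarchical blocks with strictly
    increasing widths, each halving the spatial size -> efficient channel
    attention on top.  With four blocks the total stride is 32, matching
    the MobileNetV3 track.
    """

    def __init__(self, channels: tuple[int, ...] = (32, 64, 128, 256),
                 stem_channels: int = 16, lga_groups: int = 4):
        super().__init__()
        self.stem = PushPull2d(3, stem_channels, kernel_size=5, alpha=1.0, stride=2)
        self.stem_bn = nn.BatchNorm2d(stem_channels)
        blocks = []
        in_ch = stem_channels
        for width in channels:
            blocks.append(HierarchicalBlock(in_ch, width, downsample=True,
                                            lga_groups=lga_groups))
            in_ch = width
        self.blocks = nn.Sequential(*blocks)
        self.eca = ECA(in_ch)
        self.out_channels = in_ch

    def forward(self, img: Tensor) -> Tensor:
        min_size = 2 ** (len(self.blocks.layers) + 1)
        if img.shape[2] < min_size or img.shape[3] < min_size:
            raise ValueError(f"input smaller than the downsampling chain ({min_size}px)")
        x = self.stem_bn(self.stem(img))
        return self.eca(self.blocks(x))


class DualTrackNet(nn.Module):
    """The full dual-track model: both tracks, MCA + SPP fusion, classifier."""

    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        cfg = cfg or ModelConfig()
        self.cfg = cfg
        self.backbone = MobileNetV3Features()
        self.mcsk = MCSKBlock(FEATURE_CHANNELS, cfg.mcsk_channels,
                              sge_groups=cfg.sge_groups)
        self.hsgan = HSGAN(cfg.hsgan_channels, cfg.hsgan_stem_channels,
                           lga_groups=cfg.lga_groups)
        fused_channels = cfg.mcsk_channels + self.hsgan.out_channels
        top = cfg.input_size // 32
        if top < max(cfg.spp_levels):
            raise ValueError("input_size too small for the largest SPP level")
        self.mca = MCA(fused_channels, top, top)
        self.spp = SPP(cfg.spp_levels)
        self.head = nn.Sequential(
            nn.Dropout(cfg.fusion_dropout),
            nn.Linear(self.spp.output_length(fused_channels), cfg.head_hidden),
            nn.ReLU(),
            nn.Linear(cfg.head_hidden, cfg.num_classes),
        )

    def forward(self, img: Tensor) -> Tensor:
        t1 = self.mcsk(self.backbone(img))
        t2 = self.hsgan(img)
        if t1.shape[2:] != t2.shape[2:]:
            raise ValueError(f"track spatial sizes differ: {t1.shape} vs {t2.shape}")
        fused = self.mca(ag.concatenate([t1, t2], axis=1))
        return self.head(self.spp(fused))


class _BackboneMcskClassifier(nn.Module):
    """MobileNetV3 features + MCSK + pooled classifier (ablation variant 2)."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.features = MobileNetV3Features()
        self.mcsk = MCSKBlock(FEATURE_CHANNELS, cfg.mcsk_channels,
                              sge_groups=cfg.sge_groups)
        self.head = nn.Sequential(
            nn.Dropout(cfg.fusion_dropout),
            nn.Linear(cfg.mcsk_channels, cfg.head_hidden),
            nn.ReLU(),
            nn.Linear(cfg.head_hidden, cfg.num_classes),
        )

    def forward(self, img: Tensor) -> Tensor:
        f = ag.global_avg_pool(self.mcsk(self.features(img)))
        return self.head(f)


class _HsganClassifier(nn.Module):
    """HSGAN track processed through ECA, flattened and classified (variant 3)."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.hsgan = HSGAN(cfg.hsgan_channels, cfg.hsgan_stem_channels,
                           lga_groups=cfg.lga_groups)
        top = cfg.input_size // 32
        flat = self.hsgan.out_channels * top * top
        self.head = nn.Sequential(
            nn.Flatten(),
            nn.Dropout(cfg.fusion_dropout),
            nn.Linear(flat, cfg.head_hidden),
            nn.ReLU(),
            nn.Linear(cfg.head_hidden, cfg.num_classes),
        )

    def forward(self, img: Tensor) -> Tensor:
        return self.head(self.hsgan(img))


def build_variant(name: str, cfg: ModelConfig | None = None) -> nn.Module:
    """Build one of the four ablation configurations."""
    cfg = cfg or ModelConfig()
    if name == "backbone_only":
        return MobileNetV3(cfg.num_classes)
    if name == "backbone_mcsk":
        return _BackboneMcskClassifier(cfg)
    if name == "hsgan_only":
        return _HsganClassifier(cfg)
    if name == "full":
        return DualTrackNet(cfg)
    raise ValueError(f"unknown variant {name!r}; expected one of {VARIANTS}")


def count_parameters(model: nn.Module) -> int:
    """Total element count over all trainable tensors."""
    return model.num_parameters()


@dataclass
class FlopReport:
    macs: int
    flops: int = field(init=False)

    def __post_init__(self):
        self.flops = 2 * self.macs


def count_flops(model: nn.Module, input_size: int = 224, in_channels: int = 3,
                input_shape: tuple[int, ...] | None = None) -> FlopReport:
    """Multiply-accumulate count of one single-image forward pass.

    Convolution, matrix-multiplication and dense layers are counted at one
    MAC per multiply-add (elementwise and pooling work is not counted, the
    usual convention); the report also carries 2x MACs as FLOPs.
    """
    shape = input_shape or (1, in_channels, input_size, input_size)
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros(shape, dtype=np.float32))
    with ag.mac_counting() as state:
        model(x)
        macs = state["count"]
    model.train(was_training)
    return FlopReport(macs=macs // shape[0])
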