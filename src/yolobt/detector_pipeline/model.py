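"""Full detector assembly: backbone (optionally CLAC3), neck (optionally
HFGM), per-scale global-context gating (optionally GICM), three heads."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ..nn import autograd as ag
from ..nn import Module, ModuleList, Conv2d, Parameter, set_init_seed
from ..clab_backbone import CLAC3
from ..hfgm_neck import HFGM
from ..gicm import GICM
from .common import Conv, C3, SPPF, make_divisible

__all__ = ["DetectorConfig", "Detector", "Detect", "build_model",
           "COCO_ANCHORS", "STRIDES"]

STRIDES = (8, 16, 32)

COCO_ANCHORS = (
    ((10, 13), (16, 30), (33, 23)),
    ((30, 61), (62, 45), (59, 119)),
    ((116, 90), (156, 198), (373, 326)),
)


@dataclass(frozen=True)
class DetectorConfig:
    depth_multiple: float = 0.33
    width_multiple: float = 0.50
    n_classes: int = 1
    input_size: int = 640
    clab: bool = True
    hfgm: bool = True
    gicm: bool = True
    anchors: tuple = COCO_ANCHORS
    # published module widths (tuned for the width_multiple = 0.50 variant)
    gicm_branch: tuple[int, int, int] = (24, 15, 2)
    gicm_dk: int = 64
    gicm_token_pool: tuple[int, int, int] = (1600, 1600, 400)
    hfgm_hidden: tuple[int | None, int | None] = (100, None)
    se_reduction: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if len(self.anchors) != 3 or any(len(a) != 3 for a in self.anchors):
            raise ValueError("anchors must be 3 scales x 3 anchor pairs")


class Detect(Module):
    """Per-scale 1x1 prediction convolutions with detection-friendly bias init."""

    def __init__(self, n_classes: int, anchors, channels, input_size: int = 640):
        super().__init__()
        self.nc = n_classes
        self.na = len(anchors[0])
        self.no = n_classes + 5
        self.anchors = np.asarray(anchors, dtype=np.float32)  # (3, na, 2) pixels
        self.heads = ModuleList([
            Conv2d(c, self.na * self.no, 1, bias=True) for c in channels])
        for head, stride in zip(self.heads, STRIDES):
            b = head.bias.data.reshape(self.na, self.no)
            b[:, 4] += math.log(8.0 / (input_size / stride) ** 2)
            b[:, 5:] += math.log(0.6 / (self.nc - 0.99 + 1e-12))
            head.bias.data = b.reshape(-1)

    def forward(self, feats):
        return [head(f) for head, f in zip(self.heads, feats)]


class _UpsampleConcat(Module):
    """Baseline top-down fusion: nearest x2 upsample + channel concat."""

    def __init__(self):
        super().__init__()

    def forward(self, high, low):
        return ag.concat([ag.upsample_nearest2d(high, 2), low], axis=1)


class Detector(Module):
    def __init__(self, cfg: DetectorConfig):
        super().__init__()
        set_init_seed(cfg.seed)
        self.cfg = cfg
        gw, gd = cfg.width_multiple, cfg.depth_multiple

        def cw(c: int) -> int:
            return make_divisible(c * gw, 8)

        def dn(n: int) -> int:
            return max(int(round(n * gd)), 1)

        c1, c2, c3, c4, c5 = cw(64), cw(128), cw(256), cw(512), cw(1024)
        self.channels = (c3, c4, c5)
        stage = CLAC3 if cfg.clab else C3

        # backbone
        self.stem = Conv(3, c1, 6, 2, 2)
        self.conv1 = Conv(c1, c2, 3, 2)
        self.stage1 = stage(c2, c2, dn(3))
        self.conv2 = Conv(c2, c3, 3, 2)
        self.stage2 = stage(c3, c3, dn(6))
        self.conv3 = Conv(c3, c4, 3, 2)
        self.stage3 = stage(c4, c4, dn(9))
        self.conv4 = Conv(c4, c5, 3, 2)
        self.stage4 = stage(c5, c5, dn(3))
        self.sppf = SPPF(c5, c5)

        # top-down path
        self.lat1 = Conv(c5, c4, 1)
        self.lat2 = Conv(c4, c3, 1)
        if cfg.hfgm:
            self.fuse1 = HFGM(c4, c4, 2, hidden=cfg.hfgm_hidden[0],
                              se_reduction=cfg.se_reduction)
            self.fuse2 = HFGM(c3, c3, 2, hidden=cfg.hfgm_hidden[1],
                              se_reduction=cfg.se_reduction)
        else:
            self.fuse1 = _UpsampleConcat()
            self.fuse2 = _UpsampleConcat()
        self.head1 = C3(2 * c4, c4, dn(3), shortcut=False)
        self.head2 = C3(2 * c3, c3, dn(3), shortcut=False)

        # bottom-up path
        self.down1 = Conv(c3, c3, 3, 2)
        self.head3 = C3(2 * c3, c4, dn(3), shortcut=False)
        self.down2 = Conv(c4, c4, 3, 2)
        self.head4 = C3(2 * c4, c5, dn(3), shortcut=False)

        if cfg.gicm:
            self.gates = ModuleList([
                GICM(c, bw, d_k=cfg.gicm_dk, token_pool=tp,
                     reduction=cfg.se_reduction)
                for c, bw, tp in zip(self.channels, cfg.gicm_branch,
                                     cfg.gicm_token_pool)])
            head_channels = tuple(2 * c for c in self.channels)
        else:
            self.gates = None
            head_channels = self.channels

        self.detect = Detect(cfg.n_classes, cfg.anchors, head_channels,
                             cfg.input_size)

    def features(self, x):
        x = self.stem(x)
        x = self.conv1(x)
        x = self.stage1(x)
        x = self.conv2(x)
        p3 = self.stage2(x)
        x = self.conv3(p3)
        p4 = self.stage3(x)
        x = self.conv4(p4)
        p5 = self.sppf(self.stage4(x))

        t5 = self.lat1(p5)                       # C4 @ /32
        f4 = self.head1(self.fuse1(t5, p4))      # C4 @ /16
        t4 = self.lat2(f4)                       # C3 @ /16
        f3 = self.head2(self.fuse2(t4, p3))      # C3 @ /8  -> P3 out
        d4 = self.head3(ag.concat([self.down1(f3), t4], axis=1))  # P4 out
        d5 = self.head4(ag.concat([self.down2(d4), t5], axis=1))  # P5 out
        feats = [f3, d4, d5]
        if self.gates is not None:
            # global-context output rides alongside the plain features
            feats = [ag.concat([f, g(f)], axis=1)
                     for g, f in zip(self.gates, feats)]
        return feats

    def forward(self, x):
        return self.detect(self.features(x))


def build_model(cfg: DetectorConfig) -> Detector:
    return Detector(cfg)
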