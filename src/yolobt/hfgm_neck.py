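"""Hierarchical feature guidance fusion for the top-down pyramid path.

Replaces nearest-neighbor upsample + concat with: (1) a gate derived from the
globally pooled high-level descriptor, applied multiplicatively-plus-residual
to the low-level features; (2) learned sub-pixel (depth-to-space) upsampling
of the high-level features; (3) concatenation and SE recalibration. Output
width is ``2C`` (low-level channel count doubled), which matches what the
downstream stage expects from the fusion node it replaces, so no projection
follows.
"""

from __future__ import annotations

from .nn import autograd as ag
from .nn import Module, Conv2d, Linear
from .clab_backbone import SEBlock

__all__ = [
    "high_descriptor", "GuidanceGate", "apply_guidance", "SubpixelUpsample",
    "HFGM", "guidance_gate", "subpixel_upsample", "hfgm_fuse",
]


def high_descriptor(high):
    """Concatenated global max/avg pooled channel vector, shape (B, 2C')."""
    return ag.concat([ag.global_max_pool(high), ag.global_avg_pool(high)],
                     axis=1)


class GuidanceGate(Module):
    """Affine map from the 2C' descriptor to C sigmoid gates."""

    def __init__(self, c_high: int, c_low: int):
        super().__init__()
        self.fc = Linear(2 * c_high, c_low)
        self.c_low = c_low

    def forward(self, high_map):
        if high_map.shape[-1] != self.fc.in_features:
            raise ValueError(
                f"descriptor length {high_map.shape[-1]} != {self.fc.in_features}")
        return ag.sigmoid(self.fc(high_map))           # (B, C) in (0, 1)


def apply_guidance(low, gate):
    """(low * gate) + low with the gate broadcast over H x W."""
    b, c = gate.shape
    if low.shape[1] != c:
        raise ValueError(f"gate length {c} != low channels {low.shape[1]}")
    g = ag.reshape(gate, (b, c, 1, 1))
    return low * g + low


class SubpixelUpsample(Module):
    """Channel-mapping convolution + depth-to-space rearrangement.

    Maps C' -> C*r^2 channels (3x3 convolution, optionally through a 1x1
    bottleneck of width ``hidden``) and rearranges each r^2 channel block
    into an r x r spatial block.
    """

    def __init__(self, c_high: int, c_out: int, r: int, hidden: int | None = None):
        super().__init__()
        if int(r) != r or r < 1:
            raise ValueError("upsampling factor r must be a positive integer")
        self.r = int(r)
        if hidden is None:
            self.reduce = None
            self.conv = Conv2d(c_high, c_out * r * r, 3, padding=1, bias=True)
        else:
            self.reduce = Conv2d(c_high, hidden, 1, bias=True)
            self.conv = Conv2d(hidden, c_out * r * r, 3, padding=1, bias=True)

    def forward(self, high):
        y = high if self.reduce is None else ag.silu(self.reduce(high))
        y = self.conv(y)
        if self.r == 1:
            return y
        return ag.pixel_shuffle(y, self.r)


class HFGM(Module):
    """Full guidance module: gate low level, subpixel-upsample high level,
    concat and SE-recalibrate. Output channels = 2 * c_low."""

    def __init__(self, c_high: int, c_low: int, r: int = 2,
                 hidden: int | None = None, se_reduction: int = 16):
        super().__init__()
        self.gate = GuidanceGate(c_high, c_low)
        self.up = SubpixelUpsample(c_high, c_low, r, hidden=hidden)
        self.se = SEBlock(2 * c_low, se_reduction)
        self.r = r

    def forward(self, high, low):
        hb, hc, hh, hw = high.shape
        lb, lc, lh, lw = low.shape
        if lh != self.r * hh or lw != self.r * hw:
            raise ValueError(
                f"low spatial dims {lh}x{lw} must be r={self.r} times "
                f"high {hh}x{hw}")
        gate = self.gate(high_descriptor(high))
        low_guided = apply_guidance(low, gate)
        high_up = self.up(high)
        return self.se(ag.concat([low_guided, high_up], axis=1))


# -- functional wrappers -----------------------------------------------------


def guidance_gate(high_map, module: GuidanceGate):
    return module(high_map)


def subpixel_upsample(high, module: SubpixelUpsample):
    return module(high)


def hfgm_fuse(low_guided, high_up, se: SEBlock):
    return se(ag.concat([low_guided, high_up], axis=1))
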