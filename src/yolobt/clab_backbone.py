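"""Cross-layer attention bottleneck (CLAB) backbone blocks.

Each bottleneck of a CLAC3 stage computes channel attention (shared-MLP
average+max pooling, sigmoid) and a 7x7 spatial attention map; the spatial
maps of all bottlenecks so far in the stage are fused by the cross-layer
attention module (CLAM: concatenate, SE-recalibrate, 1x1-fuse to one
channel, no terminal sigmoid). The fused map gates the bottleneck's
convolutional output, which is then smoothed by an SE block before the
residual addition. The attention history is stage-local: it starts empty at
every CLAC3 stage (spatial dimensions differ across stages).
"""

from __future__ import annotations

from .nn import autograd as ag
from .nn import Module, ModuleList, Conv2d, Linear
from .blocks import Conv

__all__ = [
    "SEBlock", "ChannelAttention", "SpatialAttention", "CLAM",
    "CLABottleneck", "CLAC3",
    "se_recalibrate", "channel_attention", "spatial_attention",
    "clam_fuse", "clab_forward", "clac3_forward",
]


class SEBlock(Module):
    """Squeeze-and-excitation: global average pool -> bottleneck MLP -> sigmoid
    gates scaling each channel."""

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden)
        self.fc2 = Linear(hidden, channels)
        self.channels = channels

    def gates(self, x):
        if x.shape[1] != self.channels:
            raise ValueError(f"SEBlock expects {self.channels} channels, "
                             f"got {x.shape[1]}")
        z = ag.global_avg_pool(x)                      # (B, C)
        return ag.sigmoid(self.fc2(ag.relu(self.fc1(z))))

    def forward(self, x):
        s = self.gates(x)
        b, c = s.shape
        return x * ag.reshape(s, (b, c, 1, 1))


class ChannelAttention(Module):
    """CBAM channel attention: sigmoid(MLP(avg) + MLP(max)), shared MLP."""

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, bias=False)
        self.fc2 = Linear(hidden, channels, bias=False)
        self.channels = channels

    def weights(self, x):
        if x.shape[1] != self.channels:
            raise ValueError(f"ChannelAttention expects {self.channels} "
                             f"channels, got {x.shape[1]}")
        avg = self.fc2(ag.relu(self.fc1(ag.global_avg_pool(x))))
        mx = self.fc2(ag.relu(self.fc1(ag.global_max_pool(x))))
        return ag.sigmoid(avg + mx)                    # (B, C)

    def forward(self, x):
        m = self.weights(x)
        b, c = m.shape
        return m, x * ag.reshape(m, (b, c, 1, 1))


class SpatialAttention(Module):
    """Channel-wise avg/max maps stacked and convolved 7x7, sigmoid gate."""

    def __init__(self, kernel_size: int = 7):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel_size, padding=kernel_size // 2, bias=True)

    def forward(self, x):
        avg = ag.mean(x, axis=1, keepdims=True)
        mx = ag.max_(x, axis=1, keepdims=True)
        return ag.sigmoid(self.conv(ag.concat([avg, mx], axis=1)))


class CLAM(Module):
    """Cross-layer fusion of n spatial maps: concat -> SE -> 1x1 to one channel.

    No terminal sigmoid; boundedness is restored downstream by the SE block
    applied to the gated features.
    """

    def __init__(self, n_maps: int, reduction: int = 16):
        super().__init__()
        self.n_maps = n_maps
        self.se = SEBlock(n_maps, reduction)
        self.fuse = Conv2d(n_maps, 1, 1, bias=True)

    def forward(self, maps: list):
        if len(maps) != self.n_maps:
            raise ValueError(f"CLAM built for {self.n_maps} maps, got {len(maps)}")
        hw = maps[0].shape[2:]
        for m in maps:
            if m.shape[2:] != hw:
                raise ValueError("spatial attention maps differ in H x W")
        stacked = ag.concat(maps, axis=1) if len(maps) > 1 else maps[0]
        return self.fuse(self.se(stacked))


class CLABottleneck(Module):
    """Bottleneck with CBAM attention, cross-layer fusion and SE smoothing.

    ``layer_index`` is the 1-based position within the stage, which fixes the
    number of attention maps the CLAM fuses.
    """

    def __init__(self, c1: int, c2: int, layer_index: int,
                 shortcut: bool = True, e: float = 1.0, reduction: int = 16):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 1)
        self.cv2 = Conv(c_, c2, 3)
        self.channel_att = ChannelAttention(c2, reduction)
        self.spatial_att = SpatialAttention()
        self.clam = CLAM(layer_index, reduction)
        self.out_se = SEBlock(c2, reduction)
        self.add = shortcut and c1 == c2
        self.layer_index = layer_index

    def forward(self, x, history: list):
        if len(history) != self.layer_index - 1:
            raise ValueError(
                f"bottleneck {self.layer_index} expects {self.layer_index - 1} "
                f"history maps, got {len(history)}")
        b_n = self.cv2(self.cv1(x))                 # bottleneck conv output
        _, b_prime = self.channel_att(b_n)
        s_n = self.spatial_att(b_prime)
        final_s = self.clam(history + [s_n])
        out = self.out_se(final_s * b_n)
        history.append(s_n)
        if self.add:
            out = x + out
        return out, history


class CLAC3(Module):
    """C3 stage whose bottlenecks share a stage-local attention history."""

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = True,
                 e: float = 0.5, reduction: int = 16):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 1)
        self.cv2 = Conv(c1, c_, 1)
        self.cv3 = Conv(2 * c_, c2, 1)
        self.m = ModuleList([
            CLABottleneck(c_, c_, layer_index=i + 1, shortcut=shortcut,
                          reduction=reduction)
            for i in range(n)])

    def forward(self, x):
        history: list = []
        y = self.cv1(x)
        for blk in self.m:
            y, history = blk(y, history)
        return self.cv3(ag.concat([y, self.cv2(x)], axis=1))


# ---------------------------------------------------------------------------
# Functional forms of the operations (thin wrappers over the modules)
# ---------------------------------------------------------------------------


def se_recalibrate(x, block: SEBlock):
    return block(x)


def channel_attention(x, module: ChannelAttention):
    return module(x)


def spatial_attention(x, module: SpatialAttention):
    return module(x)


def clam_fuse(history: list, s_n, module: CLAM):
    return module(list(history) + [s_n])


def clab_forward(x, history: list, block: CLABottleneck):
    return block(x, history)


def clac3_forward(x, stage: CLAC3):
    return stage(x)
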