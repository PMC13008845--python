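"""Global-context gating before the prediction heads.

An inception-style local branch (parallel 1/3/5/7/9 convolutions, channel
attention, 1x1 reduction, sigmoid) produces a single-channel local gate.
The global branch applies spatial attention to the input, projects it with
1x1 convolutions to key/query/value token sequences (the value gated by the
local map), and mixes them with single-head scaled dot-product attention.
When the spatial grid exceeds ``token_pool`` tokens, tokens are average-
pooled by an integer factor before attention and the result is upsampled
back. The value projection keeps the input width, so the module output
replaces the head input one-for-one.
"""

from __future__ import annotations

import math

from .nn import autograd as ag
from .nn import Module, ModuleList, Conv2d
from .clab_backbone import ChannelAttention, SpatialAttention
from .blocks import Conv

__all__ = ["LocalBranch", "GICM", "local_branch", "global_gate",
           "qkv_project", "attention_mix", "KERNEL_SET"]

KERNEL_SET = (1, 3, 5, 7, 9)


class LocalBranch(Module):
    """Five parallel convolutions -> concat -> channel attention -> 1x1 ->
    sigmoid, producing a (B, 1, H, W) gate in (0, 1)."""

    def __init__(self, c_in: int, branch_width: int, reduction: int = 16):
        super().__init__()
        self.branches = ModuleList([
            Conv(c_in, branch_width, k, p=k // 2) for k in KERNEL_SET])
        c_cat = branch_width * len(KERNEL_SET)
        self.channel_att = ChannelAttention(c_cat, reduction)
        self.reduce = Conv2d(c_cat, 1, 1, bias=True)

    def forward(self, x):
        feats = [b(x) for b in self.branches]
        cat = ag.concat(feats, axis=1)
        _, reweighted = self.channel_att(cat)
        return ag.sigmoid(self.reduce(reweighted))


def attention_mix(k, q, v, d_k: int):
    """softmax(Q K^T / sqrt(d_k)) V over token sequences (B, T, d)."""
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    scores = ag.matmul(q, ag.transpose(k, (0, 2, 1))) * (1.0 / math.sqrt(d_k))
    weights = ag.softmax(scores, axis=-1)
    return ag.matmul(weights, v), weights


def _tokens(x):
    """(B, C, H, W) -> (B, H*W, C)."""
    b, c, h, w = x.shape
    return ag.transpose(ag.reshape(x, (b, c, h * w)), (0, 2, 1))


class GICM(Module):
    def __init__(self, c_in: int, branch_width: int, d_k: int = 64,
                 token_pool: int = 400, reduction: int = 16):
        super().__init__()
        if token_pool < 1:
            raise ValueError("token_pool must be >= 1")
        self.local = LocalBranch(c_in, branch_width, reduction)
        self.spatial_att = SpatialAttention()
        self.k_proj = Conv2d(c_in, d_k, 1, bias=True)
        self.q_proj = Conv2d(c_in, d_k, 1, bias=True)
        self.v_proj = Conv2d(c_in, c_in, 1, bias=True)
        self.d_k = d_k
        self.token_pool = token_pool
        self.c_in = c_in

    def global_gate(self, x):
        return x * self.spatial_att(x)

    def qkv(self, x_global, l_feature):
        k = self.k_proj(x_global)
        q = self.q_proj(x_global)
        v = self.v_proj(x_global) * l_feature   # gate broadcast over channels
        return k, q, v

    def _pool_factor(self, h: int, w: int) -> int:
        f = 1
        while (h // f) * (w // f) > self.token_pool:
            f += 1
            while h % f or w % f:
                f += 1
                if f > max(h, w):
                    raise ValueError(
                        f"cannot pool {h}x{w} grid to <= {self.token_pool} tokens")
        return f

    def forward(self, x):
        b, c, h, w = x.shape
        l_feature = self.local(x)
        x_global = self.global_gate(x)
        k, q, v = self.qkv(x_global, l_feature)
        f = self._pool_factor(h, w)
        if f > 1:
            k, q, v = (ag.avg_pool2d(t, f) for t in (k, q, v))
        hp, wp = h // f, w // f
        out, _ = attention_mix(_tokens(k), _tokens(q), _tokens(v), self.d_k)
        out = ag.reshape(ag.transpose(out, (0, 2, 1)), (b, c, hp, wp))
        if f > 1:
            out = ag.upsample_nearest2d(out, f)
        return out


# -- functional wrappers -----------------------------------------------------


def local_branch(x, module: LocalBranch):
    return module(x)


def global_gate(x, module: GICM):
    return module.global_gate(x)


def qkv_project(x_global, l_feature, module: GICM):
    return module.qkv(x_global, l_feature)
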