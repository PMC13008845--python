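"""Standard one-stage detector building blocks (conv-BN-SiLU, C3, SPPF)."""

from __future__ import annotations

from .nn import autograd as ag
from .nn import (Module, ModuleList, Conv2d, BatchNorm2d)

__all__ = ["Conv", "Bottleneck", "C3", "SPPF", "make_divisible"]


def make_divisible(x: float, divisor: int = 8) -> int:
    return max(divisor, int(round(x / divisor) * divisor))


class Conv(Module):
    """Conv2d (no bias) + BatchNorm + SiLU."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 p: int | None = None):
        super().__init__()
        self.conv = Conv2d(c1, c2, k, stride=s,
                           padding=k // 2 if p is None else p, bias=False)
        self.bn = BatchNorm2d(c2)

    def forward(self, x):
        return ag.silu(self.bn(self.conv(x)))


class Bottleneck(Module):
    def __init__(self, c1: int, c2: int, shortcut: bool = True, e: float = 1.0):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 1)
        self.cv2 = Conv(c_, c2, 3)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(Module):
    """CSP bottleneck stage with three 1x1 convolutions."""

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = True,
                 e: float = 0.5):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 1)
        self.cv2 = Conv(c1, c_, 1)
        self.cv3 = Conv(2 * c_, c2, 1)
        self.m = ModuleList([Bottleneck(c_, c_, shortcut, e=1.0)
                             for _ in range(n)])

    def forward(self, x):
        y = self.cv1(x)
        for b in self.m:
            y = b(y)
        return self.cv3(ag.concat([y, self.cv2(x)], axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three stacked 5x5 max-pools."""

    def __init__(self, c1: int, c2: int, k: int = 5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = Conv(c1, c_, 1)
        self.cv2 = Conv(c_ * 4, c2, 1)
        self.k = k

    def forward(self, x):
        y0 = self.cv1(x)
        y1 = ag.max_pool2d(y0, self.k, 1, self.k // 2)
        y2 = ag.max_pool2d(y1, self.k, 1, self.k // 2)
        y3 = ag.max_pool2d(y2, self.k, 1, self.k // 2)
        return self.cv2(ag.concat([y0, y1, y2, y3], axis=1))
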