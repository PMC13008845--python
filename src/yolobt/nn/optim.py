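"""SGD with momentum + cosine-annealed learning-rate schedule."""

from __future__ import annotations

import math

import numpy as np

from .layers import Parameter

__all__ = ["SGD", "cosine_lr"]


class SGD:
    """SGD with (heavy-ball) momentum and optional decoupled weight decay.

    ``param_groups`` is a list of dicts ``{"params": [...], "weight_decay": f}``
    so that bias/normalization parameters can be excluded from decay.
    """

    def __init__(self, param_groups, lr: float = 0.01, momentum: float = 0.937):
        if isinstance(param_groups, (list, tuple)) and param_groups and \
                isinstance(param_groups[0], Parameter):
            param_groups = [{"params": list(param_groups), "weight_decay": 0.0}]
        self.param_groups = param_groups
        self.lr = lr
        self.momentum = momentum
        self._velocity: dict[int, np.ndarray] = {}

    def zero_grad(self) -> None:
        for g in self.param_groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        for g in self.param_groups:
            wd = g.get("weight_decay", 0.0)
            for p in g["params"]:
                if p.grad is None:
                    continue
                d = p.grad.astype(np.float32)
                if wd:
                    d = d + wd * p.data
                v = self._velocity.get(id(p))
                if v is None:
                    v = np.zeros_like(p.data)
                    self._velocity[id(p)] = v
                v *= self.momentum
                v += d
                p.data -= self.lr * v


def cosine_lr(initial_lr: float, epoch: int, total_epochs: int,
              final_fraction: float = 0.01) -> float:
    """Cosine annealing from ``initial_lr`` to ``final_fraction * initial_lr``."""
    if total_epochs <= 1:
        return initial_lr
    t = min(epoch, total_epochs - 1) / (total_epochs - 1)
    lo = final_fraction * initial_lr
    return lo + 0.5 * (initial_lr - lo) * (1 + math.cos(math.pi * t))
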