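"""Layer/module abstractions on top of the autograd engine."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Module", "ModuleList", "Sequential", "Identity",
    "Conv2d", "BatchNorm2d", "Linear", "Parameter",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data: np.ndarray):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Lightweight torch-style module with recursive parameter discovery."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- (de)serialization of weights and buffers --------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for mname, m in self._named_modules():
            for bname, buf in getattr(m, "_buffers", {}).items():
                state[f"{mname}{bname}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, val in state.items():
            if name in params:
                params[name].data = np.asarray(val, dtype=np.float32).reshape(
                    params[name].shape)
            else:
                mname, bname = name.rsplit(".", 1) if "." in name else ("", name)
                target = self
                if mname:
                    for part in mname.split("."):
                        target = target._modules[part]
                target._buffers[bname] = np.asarray(val, dtype=np.float32)
                object.__setattr__(target, bname, target._buffers[bname])

    def _named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, m in self._modules.items():
            yield from m._named_modules(prefix=f"{prefix}{name}.")


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module) -> None:
        self._modules[str(len(self._list))] = module
        self._list.append(module)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self._list = list(modules)
        for i, m in enumerate(modules):
            self._modules[str(i)] = m

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Identity(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x):
        return x


def _kaiming(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator):
    bound = math.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * bound).astype(np.float32)


_INIT_RNG = np.random.default_rng(0)


def set_init_seed(seed: int) -> None:
    """Reseed the global weight-initialization RNG (call before building models)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(_kaiming(
            (out_channels, in_channels, kernel_size, kernel_size), fan_in, _INIT_RNG))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_kaiming((out_features, in_features),
                                         in_features, _INIT_RNG))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = ag.matmul(x, ag.transpose(self.weight, (1, 0)))
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm2d(Module):
    """Batch normalization with running statistics (buffers, not parameters)."""

    def __init__(self, num_features: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self._buffers = {
            "running_mean": np.zeros(num_features, dtype=np.float32),
            "running_var": np.ones(num_features, dtype=np.float32),
        }
        object.__setattr__(self, "running_mean", self._buffers["running_mean"])
        object.__setattr__(self, "running_var", self._buffers["running_var"])

    def forward(self, x: Tensor) -> Tensor:
        c = self.num_features
        if self.training:
            out, mu, var = ag.batch_norm_train(x, self.weight, self.bias,
                                               self.eps)
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var * (n / max(n - 1, 1))
            self._buffers["running_mean"] *= (1 - m)
            self._buffers["running_mean"] += m * mu
            self._buffers["running_var"] *= (1 - m)
            self._buffers["running_var"] += m * unbiased
            return out
        rm = self._buffers["running_mean"].reshape(1, c, 1, 1)
        rv = self._buffers["running_var"].reshape(1, c, 1, 1)
        scale = 1.0 / np.sqrt(rv + self.eps)
        y = (x - rm) * scale
        w = ag.reshape(self.weight, (1, c, 1, 1))
        b = ag.reshape(self.bias, (1, c, 1, 1))
        ag._add_macs(x.data.size)  # scale-and-shift: 1 MAC per element
        return y * w + b
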