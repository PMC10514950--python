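"""Layer/module abstractions over the functional ops.

Mirrors the familiar ``Module`` idiom: submodules and parameters are
registered through attribute assignment, ``state_dict`` round-trips plain
numpy arrays, and ``train()``/``eval()`` toggle batch-norm behaviour.
"""

from __future__ import annotations

import math
from collections import OrderedDict

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor

__all__ = [
    "Module", "Sequential", "Identity", "Conv2d", "BatchNorm2d", "ReLU",
    "MaxPool2d", "Upsample2x", "set_init_rng", "init_rng",
]

_INIT_RNG = np.random.default_rng(0)


def set_init_rng(rng: np.random.Generator) -> None:
    """Set the generator used for weight initialisation of new layers."""
    global _INIT_RNG
    _INIT_RNG = rng


def init_rng() -> np.random.Generator:
    return _INIT_RNG


class Module:
    def __init__(self):
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- mode / state ------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)[:5]} ...")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(p.data.dtype).copy()
        for name, b in bufs.items():
            b[...] = state[name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)

    def __iter__(self):
        return iter(self._modules.values())

    def __getitem__(self, i):
        return list(self._modules.values())[i]

    def forward(self, x: Tensor) -> Tensor:
        for m in self._modules.values():
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 stride=1, padding=0, dilation=1, groups: int = 1,
                 bias: bool = True, dtype=np.float32):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if np.isscalar(kernel_size) else kernel_size
        if in_channels % groups:
            raise ValueError("in_channels must be divisible by groups")
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        fan_out = out_channels * kh * kw // groups
        std = math.sqrt(2.0 / fan_out)  # He init, fan-out mode
        rng = init_rng()
        self.weight = Parameter(
            rng.normal(0.0, std, size=(out_channels, in_channels // groups, kh, kw)).astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(num_features, dtype=dtype))
        self.bias = Parameter(np.zeros(num_features, dtype=dtype))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=dtype))
        self.register_buffer("running_var", np.ones(num_features, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(x, self.weight, self.bias, self.running_mean,
                              self.running_var, training=self.training,
                              momentum=self.momentum, eps=self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.relu(x)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.upsample_nearest2x(x)
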