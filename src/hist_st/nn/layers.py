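"""Neural-network layers on top of the autodiff engine.

Initialization is Kaiming-style fan-in scaling, drawn from a numpy Generator
so every model is a pure function of its seed.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import Tensor, no_grad

__all__ = [
    "Parameter", "Module", "Sequential", "ModuleList", "Identity",
    "Conv2d", "Linear", "BatchNorm2d", "LayerNorm2d", "LayerNorm",
    "MaxPool2d", "ReLU", "Sigmoid", "GELU", "UpsampleBilinear2x",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ---------------------------------------------------------

    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, val in vars(self).items():
            sub = f"{prefix}.{name}" if prefix else name
            if isinstance(val, Module):
                yield from val.named_modules(sub)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_modules(f"{sub}.{i}")

    def named_parameters(self) -> Iterator[tuple[str, Parameter]]:
        for mprefix, mod in self.named_modules():
            for name, val in vars(mod).items():
                if isinstance(val, Parameter):
                    yield (f"{mprefix}.{name}" if mprefix else name), val

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- checkpointing -----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for mprefix, mod in self.named_modules():
            for name, val in vars(mod).items():
                if isinstance(val, np.ndarray):  # buffers (running stats)
                    key = f"{mprefix}.{name}" if mprefix else name
                    state[key] = val.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {}
        for mprefix, mod in self.named_modules():
            for name, val in vars(mod).items():
                if isinstance(val, np.ndarray):
                    buffers[f"{mprefix}.{name}" if mprefix else name] = (mod, name)
        for key, arr in state.items():
            if key in params:
                params[key].data = np.asarray(arr, dtype=np.float32)
            elif key in buffers:
                mod, name = buffers[key]
                setattr(mod, name, np.asarray(arr))
            else:
                raise KeyError(f"unexpected key in state dict: {key}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self.mods = list(mods)

    def __iter__(self):
        return iter(self.mods)

    def __len__(self):
        return len(self.mods)

    def __getitem__(self, i):
        return self.mods[i]

    def append(self, m):
        self.mods.append(m)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 groups: int = 1, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        k = kernel_size
        fan_in = (in_channels // groups) * k * k
        self.weight = Parameter(_kaiming(rng, (out_channels, in_channels // groups, k, k), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding,
                        self.dilation, self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float64)
        self.running_var = np.ones(num_features, dtype=np.float64)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        shape = (1, c, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 2, 3), keepdims=True)
            with no_grad():
                m = self.momentum
                n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                unbias = n / max(n - 1, 1)
                self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c)
                self.running_var = (1 - m) * self.running_var + m * unbias * var.data.reshape(c)
        else:
            mu = Tensor(self.running_mean.reshape(shape).astype(x.data.dtype))
            var = Tensor(self.running_var.reshape(shape).astype(x.data.dtype))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


class LayerNorm2d(Module):
    """Layer normalization over the channel axis of NCHW maps (ConvNeXt style)."""

    def __init__(self, num_channels: int, eps: float = 1e-6):
        super().__init__()
        self.weight = Parameter(np.ones(num_channels))
        self.bias = Parameter(np.zeros(num_channels))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        mu = x.mean(axis=1, keepdims=True)
        var = ((x - mu) * (x - mu)).mean(axis=1, keepdims=True)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        shape = (1, c, 1, 1)
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


class LayerNorm(Module):
    """Layer normalization over the last axis of a 2-D (batch, features) tensor."""

    def __init__(self, num_features: int, eps: float = 1e-6):
        super().__init__()
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) * (x - mu)).mean(axis=-1, keepdims=True)
        return ((x - mu) / ((var + self.eps) ** 0.5)) * self.weight + self.bias


class MaxPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.maxpool2x2()


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class GELU(Module):
    def forward(self, x):
        return x.gelu()


class UpsampleBilinear2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        return x.resize_bilinear(2 * h, 2 * w)
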