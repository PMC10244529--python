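"""Module/parameter containers built on the autograd tensor.

The surface intentionally mirrors the conventions every deep-learning
practitioner knows: ``Module`` with ``parameters()`` / ``train()`` / ``eval()``
/ ``state_dict()``, ``Conv2d`` with He-style init, ``BatchNorm2d`` with running
statistics, ``Sequential`` composition.
"""

from __future__ import annotations

import math
from collections import OrderedDict

import numpy as np

from . import functional as F
from .tensor import Tensor, default_rng

__all__ = [
    "Parameter", "Module", "Sequential", "Conv2d", "Linear", "BatchNorm2d",
    "ReLU", "LeakyReLU", "Sigmoid", "MaxPool2d", "Dropout", "Identity",
    "count_parameters",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self._modules: "OrderedDict[str, Module]" = OrderedDict()
        self._params: "OrderedDict[str, Parameter]" = OrderedDict()
        self._buffers: "OrderedDict[str, np.ndarray]" = OrderedDict()
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", OrderedDict())[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield prefix + n, p
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix + mn + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield prefix + n, b
        for mn, m in self._modules.items():
            yield from m.named_buffers(prefix + mn + ".")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        out = {}
        for n, p in self.named_parameters():
            out["param." + n] = p.data.copy()
        for n, b in self.named_buffers():
            out["buffer." + n] = b.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        params = {n: p for n, p in self.named_parameters()}
        buffers = {n: b for n, b in self.named_buffers()}
        for key, value in state.items():
            kind, name = key.split(".", 1)
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unexpected parameter {name!r} in checkpoint")
                if params[name].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {name!r}: checkpoint {value.shape}, "
                        f"model {params[name].data.shape}")
                params[name].data[...] = value
            else:
                buffers[name][...] = value

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)

    def __iter__(self):
        return iter(self._modules.values())

    def forward(self, x):
        for m in self._modules.values():
            x = m(x)
        return x


class Conv2d(Module):
    """2-D convolution with He-normal weight init (fan-in, ReLU gain)."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, bias=True):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        self.in_channels, self.out_channels = in_channels, out_channels
        self.stride, self.padding = stride, padding
        fan_in = in_channels * kh * kw
        std = math.sqrt(2.0 / fan_in)
        rng = default_rng()
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels, kh, kw)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True):
        super().__init__()
        bound = 1.0 / math.sqrt(in_features)
        rng = default_rng()
        self.weight = Parameter(rng.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_features)) if bias else None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, num_features, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x):
        return F.batch_norm2d(x, self.weight, self.bias, self.running_mean,
                              self.running_var, self.training, self.momentum, self.eps)


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.01):
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x):
        return F.leaky_relu(x, self.negative_slope)


class Sigmoid(Module):
    def forward(self, x):
        return F.sigmoid(x)


class MaxPool2d(Module):
    def __init__(self, kernel_size, stride=None, padding=0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class Dropout(Module):
    def __init__(self, p: float = 0.5):
        super().__init__()
        self.p = p

    def forward(self, x):
        return F.dropout(x, self.p, self.training)


class Identity(Module):
    def forward(self, x):
        return x


def count_parameters(model: Module) -> int:
    """Total number of trainable parameter elements in ``model``."""
    return sum(p.data.size for p in model.parameters())
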