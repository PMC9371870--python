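"""Layer modules: parameter containers over the autograd ops.

Weight initialisation takes an explicit ``numpy.random.Generator`` so that
model construction is a pure function of a seed.
"""

from __future__ import annotations

from typing import Iterator, List

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterator["Module"]:
        def walk(v):
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    yield from walk(item)

        yield self
        for v in self.__dict__.values():
            yield from walk(v)

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> dict:
        """Flat name -> array mapping of all parameters and buffers."""
        out = {}
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    out[f"{i}.{k}"] = v.data
                elif isinstance(v, np.ndarray):
                    out[f"{i}.{k}"] = v
        return out

    def load_state_arrays(self, state: dict):
        for i, m in enumerate(self.modules()):
            for k, v in list(m.__dict__.items()):
                key = f"{i}.{k}"
                if key in state:
                    if isinstance(v, Tensor):
                        v.data = np.asarray(state[key], dtype=v.data.dtype)
                    else:
                        setattr(m, k, np.asarray(state[key]))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Tensor(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = ag.batch_norm2d_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
            return out
        return ag.batch_norm2d_eval(x, self.gamma, self.beta,
                                    self.running_mean, self.running_var, self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(1.0 / in_features)
        self.weight = Tensor(rng.uniform(-bound, bound, (out_features, in_features)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.weight, self.bias)


class ConvBnRelu(Module):
    """3x3 (or kxk) convolution + batch norm + ReLU, the workhorse block."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng,
                 stride: int = 1, padding: int = 1):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, rng, stride=stride, padding=padding, bias=False)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(self.bn(self.conv(x)))
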