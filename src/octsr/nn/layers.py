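"""Network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor
from . import functional as F

DTYPE = np.float32


class Module:
    """Base class: children and parameters are discovered from attributes."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict):
        mine = dict(self.named_parameters())
        missing = set(mine) - set(state)
        extra = set(state) - set(mine)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in mine.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"{k}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU-family nets
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)).astype(DTYPE))
        self.bias = Parameter(np.zeros(c_out, dtype=DTYPE)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)

    def named_parameters(self, prefix: str = ""):
        yield f"{prefix}weight", self.weight
        if self.bias is not None:
            yield f"{prefix}bias", self.bias


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, *, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(d_in, d_out)).astype(DTYPE))
        self.bias = Parameter(np.zeros(d_out, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class InstanceNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c, dtype=DTYPE))
        self.beta = Parameter(np.zeros(c, dtype=DTYPE))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.instance_norm(x, self.gamma, self.beta, self.eps)


class ResidualBlock(Module):
    """conv3x3 -> IN -> ReLU -> conv3x3 -> IN, plus identity skip."""

    def __init__(self, channels: int, *, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.norm1 = InstanceNorm2d(channels)
        self.conv2 = Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.norm2 = InstanceNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        y = self.norm1(self.conv1(x)).relu()
        y = self.norm2(self.conv2(y))
        return x + y


class Adam:
    """Adam optimizer (bias-corrected first/second moment estimates)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {"t": self.t, "lr": self.lr,
                "m": [m.copy() for m in self.m], "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        self.lr = float(state["lr"])
        self.m = [np.asarray(m).copy() for m in state["m"]]
        self.v = [np.asarray(v).copy() for v in state["v"]]
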