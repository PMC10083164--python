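"""Layer/module abstractions over the autodiff engine."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor
from . import functional as F

__all__ = ["Module", "Conv2d", "InstanceNorm2d", "Linear", "Identity",
    "ReLU", "LeakyReLU", "Tanh"]


class Module:
    """Minimal container: children and parameters are discovered from
    attributes; ``state_dict`` flattens them under dotted names."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{i}", item

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, v in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {v.data.shape}")
            v.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 stride: int = 1, padding: int = 0, *, rng: np.random.Generator):
        # He-style fan-in init, standard for ReLU conv stacks
        fan_in = in_ch * kernel * kernel
        scale = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, scale, (out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        bound = 1.0 / math.sqrt(fan_in)
        self.bias = Tensor(rng.uniform(-bound, bound, out_ch), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias,
                        stride=self.stride, padding=self.padding)


class InstanceNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(ch), requires_grad=True)
        self.beta = Tensor(np.zeros(ch), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.instance_norm(x, self.gamma, self.beta, self.eps)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, *, rng: np.random.Generator):
        scale = math.sqrt(2.0 / in_f)
        self.weight = Tensor(rng.normal(0.0, scale, (in_f, out_f)), requires_grad=True)
        bound = 1.0 / math.sqrt(in_f)
        self.bias = Tensor(rng.uniform(-bound, bound, out_f), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()
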