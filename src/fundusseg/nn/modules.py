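"""Neural-network module system on top of the autodiff tensor.

Mirrors the familiar Module/Parameter design: parameters and submodules are
registered on attribute assignment, ``named_parameters`` walks the tree, and
``state_dict`` returns plain NumPy arrays.  Freezing is a per-parameter flag
(``Parameter.frozen``); frozen parameters still participate in the forward
pass but are skipped by the optimizer and excluded from gradient bookkeeping
by the caller.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
from scipy.stats import truncnorm

from .tensor import (
    Tensor,
    batchnorm2d,
    batchnorm2d_eval,
    conv2d,
    groupnorm2d,
    matmul,
    tmean,
    transpose,
)


class Parameter(Tensor):
    __slots__ = ("frozen",)

    def __init__(self, data, frozen: bool = False):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
        self.frozen = frozen


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated normal (mean 0, truncation at ±2σ) — standard ViT init."""
    return truncnorm.rvs(-2.0, 2.0, scale=std, size=shape, random_state=rng).astype(
        np.float32
    )


def _fan_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ------------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def trainable_parameters(self) -> Iterator[Parameter]:
        for p in self.parameters():
            if not p.frozen:
                yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        out.update({name: b.copy() for name, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        own_params = dict(self.named_parameters())
        own_buffers = {n: m for n, m in self._walk_buffer_owners()}
        missing = []
        for name, p in own_params.items():
            if name in state:
                arr = np.asarray(state[name], dtype=np.float32)
                if arr.shape != p.data.shape:
                    raise ValueError(
                        f"shape mismatch for '{name}': got {arr.shape}, expected {p.data.shape}"
                    )
                p.data = arr.copy()
            else:
                missing.append(name)
        for name, (owner, attr) in own_buffers.items():
            if name in state:
                owner._set_buffer(attr, np.asarray(state[name]).copy())
            else:
                missing.append(name)
        if strict and missing:
            raise KeyError(f"missing keys in state dict: {missing[:5]}...")
        return missing

    def _walk_buffer_owners(self, prefix: str = ""):
        for name in self._buffers:
            yield prefix + name, (self, name)
        for name, m in self._modules.items():
            yield from m._walk_buffer_owners(prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)
        self._layers = layers

    def forward(self, x):
        for layer in self._layers:
            x = layer(x)
        return x


class Linear(Module):
    """y = x @ W.T + b, weight stored (out, in) for checkpoint compatibility."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(_fan_uniform(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        wt = transpose(self.weight, (1, 0))
        y = matmul(x, wt)
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 padding: int = 0, bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_fan_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = tmean(x, axis=-1, keepdims=True)
        xc = x - mu
        var = tmean(xc * xc, axis=-1, keepdims=True)
        y = xc * (var + self.eps) ** -0.5
        return y * self.weight + self.bias


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            out, mu, var = batchnorm2d(x, self.weight, self.bias, eps=self.eps)
            n = x.size // c
            unbiased = var * (n / max(n - 1, 1))
            self._set_buffer(
                "running_mean",
                ((1 - self.momentum) * self.running_mean + self.momentum * mu).astype(
                    np.float32
                ),
            )
            self._set_buffer(
                "running_var",
                ((1 - self.momentum) * self.running_var + self.momentum * unbiased).astype(
                    np.float32
                ),
            )
            return out
        return batchnorm2d_eval(
            x, self.weight, self.bias, self.running_mean, self.running_var, eps=self.eps
        )


class GroupNorm(Module):
    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        super().__init__()
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.groups = groups
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return groupnorm2d(x, self.weight, self.bias, self.groups, eps=self.eps)


def make_norm2d(kind: str, channels: int, groups: int = 8) -> Module:
    if kind == "batch":
        return BatchNorm2d(channels)
    if kind == "group":
        return GroupNorm(min(groups, channels), channels)
    raise ValueError(f"unknown norm kind: {kind!r}")
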