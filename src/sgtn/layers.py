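"""Parameterized layers shared by the network blocks.

All layers hold their weights as autodiff :class:`~sgtn.nn.Tensor` objects
and expose ``named_parameters()`` for optimization and checkpointing.
Weights are initialized Kaiming-uniform (fan-in), biases zero, from an
explicit ``numpy.random.Generator`` so every build is reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from .nn import Tensor, conv2d_same

__all__ = ["kaiming_uniform", "Linear", "Conv2d", "LayerNorm", "Module"]

DTYPE = np.float32


def kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                    fan_in: int) -> np.ndarray:
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Module:
    """Tiny parameter-container base class."""

    def named_parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for sub, t in val.named_parameters().items():
                    out[f"{name}.{sub}"] = t
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, t in item.named_parameters().items():
                            out[f"{name}.{i}.{sub}"] = t
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        self.weight = Tensor(kaiming_uniform(rng, (in_features, out_features),
                                             in_features), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=DTYPE),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """Size-preserving convolution, channels-last, stride 1."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int], rng: np.random.Generator):
        kh, kw = kernel
        fan_in = kh * kw * in_channels
        self.weight = Tensor(
            kaiming_uniform(rng, (kh, kw, in_channels, out_channels), fan_in),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=DTYPE),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d_same(x, self.weight, self.bias)


class LayerNorm(Module):
    """Normalization over the last axis with learnable scale and shift."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.scale = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.shift = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * (var + self.eps) ** -0.5
        return xhat * self.scale + self.shift
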