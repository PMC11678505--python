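"""Minimal neural-network building blocks over the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv3d

__all__ = ["Module", "Parameter", "Conv3d", "Linear", "Sequential", "SiLU", "sinusoidal_embedding"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, zero_grad, flat state (de)serialisation."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    """3x3x3 (or kxkxk) convolution, He-normal init, 'same' padding at stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k**3
        w = rng.standard_normal((c_out, c_in, k, k, k)) * np.sqrt(2.0 / fan_in)
        self.weight = Parameter(w.astype(dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))
        self.stride = stride
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, pad=self.k // 2)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        w = rng.standard_normal((n_in, n_out)) * np.sqrt(1.0 / n_in)
        self.weight = Parameter(w.astype(dtype))
        self.bias = Parameter(np.zeros(n_out, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x


def sinusoidal_embedding(t: int, dim: int = 16, max_period: float = 10000.0) -> np.ndarray:
    """Transformer-style timestep embedding (numpy constant, no gradient)."""
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / half)
    ang = t * freqs
    return np.concatenate([np.sin(ang), np.cos(ang)])
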