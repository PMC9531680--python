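"""Layer/module abstractions over the autodiff tensors.

Every layer draws its initial weights from the ``numpy.random.Generator``
passed at construction, so a model built from a seeded generator is fully
reproducible.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor, concat

__all__ = [
    "Module", "Parameter", "Linear", "Conv2d", "Sequential", "ReLU",
    "LeakyReLU", "LayerNorm", "MultiHeadSelfAttention", "TransformerBlock",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        stack: list[object] = [self]
        while stack:
            obj = stack.pop()
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                stack.extend(obj.__dict__.values())
            elif isinstance(obj, (list, tuple)):
                stack.extend(obj)
            elif isinstance(obj, dict):
                stack.extend(obj.values())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def param_shapes(self) -> list[tuple[int, ...]]:
        return [p.shape for p in self.parameters()]

    def state_list(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_list(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state length mismatch")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(arr, dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = Parameter(rng.normal(0.0, scale, size=(c_out, c_in, k, k)))
        self.b = Parameter(np.zeros(c_out))
        self.stride = stride
        self.padding = k // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return self.gamma * (xc / (var + self.eps).sqrt()) + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"embedding dim {dim} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.dim = dim
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, t, e = x.shape
        h, d = self.n_heads, e // self.n_heads

        def heads(lin: Linear) -> Tensor:
            return lin(x).reshape(b, t, h, d).transpose(0, 2, 1, 3)

        q, k, v = heads(self.q), heads(self.k), heads(self.v)
        att = F.softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d)), axis=-1)
        y = (att @ v).transpose(0, 2, 1, 3).reshape(b, t, e)
        return self.out(y)


class TransformerBlock(Module):
    """Pre-norm transformer encoder block (attention + 2-layer MLP)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 mlp_ratio: int = 2):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, dim * mlp_ratio, rng)
        self.fc2 = Linear(dim * mlp_ratio, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.fc2(self.fc1(self.ln2(x)).relu())
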