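"""Network building blocks on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv1d, layer_norm

__all__ = ["Module", "Linear", "LayerNorm", "Conv1d", "softmax", "seeded_rngs"]


def seeded_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators spawned from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


class Module:
    """Lightweight parameter container with recursive traversal."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            items = value if isinstance(value, (list, tuple)) else [value]
            for item in items:
                if isinstance(item, Tensor) and item.requires_grad:
                    if id(item) not in seen:
                        seen.add(id(item))
                        params.append(item)
                elif isinstance(item, Module):
                    for p in item.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = a.copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    """Affine map ``x @ W + b`` with Kaiming-style fan-in initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, gain: float = 2.0):
        scale = np.sqrt(gain / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    """Layer normalisation over the last axis with learnable gain and bias."""

    def __init__(self, width: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(width), requires_grad=True)
        self.bias = Tensor(np.zeros(width), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gain, self.bias, self.eps)


class Conv1d(Module):
    """Stride-1 1-D convolution layer with 'same' padding for odd kernels."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        same_padding: bool = True,
        zero_init: bool = False,
    ):
        if zero_init:
            w = np.zeros((c_out, c_in, kernel))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / (c_in * kernel)), size=(c_out, c_in, kernel))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.padding = (kernel - 1) // 2 if same_padding else 0

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, padding=self.padding)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (shift treated as constant)."""
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)
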