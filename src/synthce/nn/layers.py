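"""Layers for the translation networks: convolution, transpose convolution,
instance normalisation and dropout, with He-initialised weights."""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, conv_transpose_nd, convnd

__all__ = ["Module", "ConvNd", "ConvTransposeNd", "InstanceNorm", "dropout"]


class Module:
    """Base class providing recursive parameter discovery."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=full + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{full}.{i}."))
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    return Tensor(rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape),
                  requires_grad=True)


class ConvNd(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, nd: int,
                 stride: int = 1, padding: int | None = None,
                 rng: np.random.Generator):
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel ** nd
        self.weight = _he_init(rng, (out_ch, in_ch) + (kernel,) * nd, fan_in)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return convnd(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding)


class ConvTransposeNd(Module):
    """Stride-2 learnable upsampling (output spatial size doubles)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 4, *, nd: int,
                 stride: int = 2, padding: int = 1, rng: np.random.Generator):
        self.stride = stride
        self.padding = padding
        fan_in = in_ch * kernel ** nd
        self.weight = _he_init(rng, (in_ch, out_ch) + (kernel,) * nd, fan_in)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose_nd(x, self.weight, self.bias, stride=self.stride,
                                 padding=self.padding)


class InstanceNorm(Module):
    """Per-sample, per-channel normalisation over spatial axes with a learnable
    affine, as used throughout style-transfer generators."""

    def __init__(self, n_ch: int, *, nd: int, eps: float = 1e-5):
        self.eps = eps
        shape = (1, n_ch) + (1,) * nd
        self.gamma = Tensor(np.ones(shape), requires_grad=True)
        self.beta = Tensor(np.zeros(shape), requires_grad=True)
        self._spatial = tuple(range(2, 2 + nd))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=self._spatial, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=self._spatial, keepdims=True)
        normed = centred * (var + self.eps) ** -0.5
        return normed * self.gamma + self.beta


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; the mask is drawn from `rng` so inference runs can be
    reproduced with a fixed seed (the adversarial-with-supervision paradigm
    keeps dropout on at inference)."""
    if p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)
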