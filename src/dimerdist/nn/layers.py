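"""Network building blocks: convolution, Maxout, RCIN, SE and spatial gates.

All layers operate on a single (H, W, C) example — training uses batch
size 1, so no batch axis is carried. Weights are float32 ``Tensor``s with
``requires_grad=True``; initialisation is He-style from a caller-supplied
``numpy.random.Generator`` so builds are bit-reproducible per seed.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

EPS = 1e-6  # standardization epsilon used in every normalization branch


class Module:
    """Base class with recursive parameter discovery."""

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

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def __call__(self, x):
        return self.forward(x)


class Conv2d(Module):
    """Same-padding stride-1 convolution; ``counted`` marks layers that
    participate in the architecture's conv-layer tally."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 counted: bool = True, role: str = "trunk"):
        scale = np.sqrt(2.0 / (kernel * kernel * cin))
        self.weight = Tensor(
            rng.standard_normal((kernel, kernel, cin, cout)) * scale,
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.filters = cout
        self.kernel = kernel
        self.counted = counted
        self.role = role

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias)


class Maxout(Module):
    """Channel reduction by elementwise max over consecutive channel groups."""

    def __init__(self, groups: int):
        self.groups = groups

    def forward(self, x: Tensor) -> Tensor:
        h, w, c = x.shape
        if c % self.groups:
            raise ValueError("maxout group mismatch")
        return x.reshape(h, w, c // self.groups, self.groups).max(axis=-1)


def _standardize(x: Tensor, axis) -> Tensor:
    m = x.mean(axis=axis, keepdims=True)
    centred = x - m
    var = (centred * centred).mean(axis=axis, keepdims=True)
    return centred / (var + EPS).sqrt()


class RCIN(Module):
    """Row / column / instance normalization in parallel, fused by 1x1 conv.

    Each branch standardizes the map along its own axes (rows, columns, or
    the whole spatial extent per channel) and applies a learnable per-channel
    affine. The three C-channel outputs are concatenated and projected back
    to C channels; the projection conv is excluded from the conv-layer tally.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        self.gammas = [Tensor(np.ones(channels), requires_grad=True) for _ in range(3)]
        self.betas = [Tensor(np.zeros(channels), requires_grad=True) for _ in range(3)]
        self.fuse = Conv2d(3 * channels, channels, 1, rng, counted=False, role="fusion")

    def named_parameters(self, prefix: str = ""):
        for i, (g, b) in enumerate(zip(self.gammas, self.betas)):
            yield f"{prefix}gamma{i}", g
            yield f"{prefix}beta{i}", b
        yield from self.fuse.named_parameters(f"{prefix}fuse.")

    def forward(self, x: Tensor) -> Tensor:
        branches = []
        for axis, g, b in zip((1, 0, (0, 1)), self.gammas, self.betas):
            branches.append(_standardize(x, axis) * g + b)
        return self.fuse(ag.concat(branches, axis=-1))


class SEBlock(Module):
    """Squeeze-and-excitation channel attention: global average pool ->
    bottleneck MLP -> sigmoid gate in (0, 1) applied channel-wise."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        hidden = max(1, channels // reduction)
        self.w1 = Tensor(
            rng.standard_normal((channels, hidden)) * np.sqrt(2.0 / channels),
            requires_grad=True,
        )
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.w2 = Tensor(
            rng.standard_normal((hidden, channels)) * np.sqrt(2.0 / hidden),
            requires_grad=True,
        )
        self.b2 = Tensor(np.zeros(channels), requires_grad=True)

    def gate(self, x: Tensor) -> Tensor:
        squeeze = x.mean(axis=(0, 1), keepdims=False).reshape(1, -1)
        hid = (squeeze @ self.w1 + self.b1).relu()
        return (hid @ self.w2 + self.b2).sigmoid()  # (1, C)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x).reshape(1, 1, -1)


class SpatialGate(Module):
    """Spatial attention: channel-mean and channel-max maps -> conv ->
    sigmoid gate in (0, 1) applied position-wise."""

    KERNEL = 7

    def __init__(self, rng: np.random.Generator):
        self.conv = Conv2d(2, 1, self.KERNEL, rng, counted=False, role="gate")

    def gate(self, x: Tensor) -> Tensor:
        pooled = ag.concat(
            [x.mean(axis=-1, keepdims=True), x.max(axis=-1, keepdims=True)], axis=-1
        )
        return self.conv(pooled).sigmoid()  # (H, W, 1)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


class ResidualBlock(Module):
    """RCIN -> conv -> ELU -> conv -> SE gate -> spatial gate -> skip add."""

    def __init__(self, channels: int, se_reduction: int, rng: np.random.Generator):
        self.norm = RCIN(channels, rng)
        self.conv1 = Conv2d(channels, channels, 3, rng)
        self.conv2 = Conv2d(channels, channels, 3, rng)
        self.se = SEBlock(channels, se_reduction, rng)
        self.spatial = SpatialGate(rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm(x)
        h = self.conv1(h).elu()
        h = self.conv2(h)
        h = self.se(h)
        h = self.spatial(h)
        return x + h
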