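"""Neural-network layers built on the autodiff tensor.

Initialisation is He-normal for convolutions and scaled-normal for dense
layers, always drawn from an explicit ``numpy.random.Generator`` so the
whole model is reproducible from one seed.
"""
from __future__ import annotations

from typing import Iterator, List, Optional, Tuple

import numpy as np

from .tensor import Tensor, conv2d, layer_norm, max_pool2d, scope

__all__ = [
    "Module",
    "Conv2d",
    "Linear",
    "LayerNorm",
    "Dropout",
    "MaxPool2d",
    "Sequential",
    "ReLU",
]


class Module:
    """Minimal module: tracks parameters, sub-modules and train/eval mode."""

    def __init__(self):
        self.training = True

    # -- parameter discovery -------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Tensor) and value.requires_grad and value._backward is None:
                yield full, value  # leaf parameters only, not cached activations
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def parameters(self) -> List[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- mode ----------------------------------------------------------------
    def train(self) -> "Module":
        self._set_mode(True)
        return self

    def eval(self) -> "Module":
        self._set_mode(False)
        return self

    def _set_mode(self, training: bool) -> None:
        self.training = training
        for value in vars(self).values():
            if isinstance(value, Module):
                value._set_mode(training)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item._set_mode(training)

    # -- state dict ----------------------------------------------------------
    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)[:5]}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def ceil_pad(size: int, kernel: int, stride: int) -> Tuple[int, int]:
    """Asymmetric zero padding so the output size is ``ceil(size / stride)``."""
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    return total // 2, total - total // 2


class Conv2d(Module):
    """Grouped 2-D convolution.

    ``padding`` is either an explicit (top, bottom, left, right) tuple or the
    string ``"ceil"``, in which case padding is computed at forward time so
    the spatial output is ``ceil(input / stride)`` (the stride schedule used
    throughout the backbone; keeps odd sizes well-defined).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int, *,
                 stride: int = 1, padding="ceil", groups: int = 1,
                 bias: bool = True, rng: np.random.Generator, name: str = "conv"):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"groups={groups} must divide in={in_channels} and out={out_channels}")
        kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        self.kernel = (kh, kw)
        fan_in = in_channels // groups * kh * kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels // groups, kh, kw))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, np.float32), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding
        self.groups = groups
        self.name = name

    def forward(self, x: Tensor) -> Tensor:
        if self.padding == "ceil":
            _, _, h, w = x.shape
            pt, pb = ceil_pad(h, self.kernel[0], self.stride)
            pl, pr = ceil_pad(w, self.kernel[1], self.stride)
            padding = (pt, pb, pl, pr)
        else:
            padding = self.padding
        with scope(self.name):
            return conv2d(x, self.weight, self.bias, stride=self.stride,
                          padding=padding, groups=self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *, bias: bool = True,
                 rng: np.random.Generator, name: str = "linear"):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), (in_features, out_features))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, np.float32), requires_grad=True) if bias else None
        self.name = name

    def forward(self, x: Tensor) -> Tensor:
        from .tensor import matmul
        with scope(self.name):
            out = matmul(x, self.weight, category="linear")
            if self.bias is not None:
                out = out + self.bias
            return out


class LayerNorm(Module):
    """Layer normalisation over the last axis with learned affine."""

    def __init__(self, dim: int, *, name: str = "norm"):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, np.float32), requires_grad=True)
        self.name = name

    def forward(self, x: Tensor) -> Tensor:
        with scope(self.name):
            return layer_norm(x) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Mask drawn from ``rng``."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, ceil_mode: bool = True):
        super().__init__()
        self.kernel, self.stride, self.ceil_mode = kernel, stride, ceil_mode

    def forward(self, x: Tensor) -> Tensor:
        with scope("maxpool"):
            return max_pool2d(x, self.kernel, self.stride, self.ceil_mode)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
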