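"""Network building blocks on top of the autodiff engine.

Modules follow the familiar construct/call pattern: a module owns
parameter tensors, ``__call__`` builds the forward graph, and
``parameters()`` walks the tree for the optimizer.  Weight
initialization is Gaussian with configurable standard deviation
(the adversarial networks use mean 0, std 0.02).
"""

from __future__ import annotations

import numpy as np

from .tensor import (Tensor, conv2d, depthwise_conv2d, interp2d, pad2d,
                     zero_dilate2d)

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "DepthwiseConv2d",
           "InstanceNorm2d", "ReLU", "LeakyReLU", "Tanh", "Sigmoid",
           "Sequential", "ResidualBlock", "Upsample2d", "bilinear_matrix"]


class Module:
    """Base class: children are discovered through instance attributes."""

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for mod in self.modules():
            for value in vars(mod).values():
                if isinstance(value, Tensor) and value.requires_grad:
                    params.append(value)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict does not match module parameters")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch")
            p.data = arr.copy()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv2d(Module):
    """``init_std=None`` selects fan-in-scaled (He) initialization."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 padding: int = 0, dilation: int = 1, bias: bool = True,
                 pad_mode: str = "constant", init_std: float | None = 0.02,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.pad_mode = pad_mode
        if init_std is None:
            init_std = np.sqrt(2.0 / (cin * kernel * kernel))
        self.weight = Tensor(rng.normal(0.0, init_std, (cout, cin, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        x = pad2d(x, self.padding, self.pad_mode)
        return conv2d(x, self.weight, self.bias, self.stride, self.dilation)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, stride: int = 1,
                 padding: int = 0, dilation: int = 1, bias: bool = True,
                 init_std: float | None = 0.02,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        if init_std is None:
            init_std = np.sqrt(2.0 / (kernel * kernel))
        self.weight = Tensor(rng.normal(0.0, init_std, (channels, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        x = pad2d(x, self.padding)
        return depthwise_conv2d(x, self.weight, self.bias, self.stride,
                                self.dilation)


class ConvTranspose2d(Module):
    """Fractionally strided convolution, built as zero-dilation + conv.

    Output size follows ``(in - 1) * stride - 2 * padding + kernel +
    output_padding``; with kernel 3, stride 2, padding 1 and
    output_padding 1 this exactly doubles the spatial extent.
    """

    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 2,
                 padding: int = 1, output_padding: int = 1, bias: bool = True,
                 init_std: float = 0.02, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = padding
        self.output_padding = output_padding
        self.kernel = kernel
        self.weight = Tensor(rng.normal(0.0, init_std, (cout, cin, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        up = zero_dilate2d(x, self.stride, extra=self.output_padding)
        up = pad2d(up, self.kernel - 1 - self.padding)
        return conv2d(up, self.weight, self.bias, stride=1)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = True):
        self.eps = eps
        if affine:
            self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
            self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        else:
            self.gamma = None
            self.beta = None

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        y = xc / (var + self.eps).sqrt()
        if self.gamma is not None:
            y = y * self.gamma + self.beta
        return y


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


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ResidualBlock(Module):
    """Two 3x3 convolutions with instance norm and a skip connection."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None,
                 pad_mode: str = "reflect"):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(channels, channels, 3, padding=1,
                            pad_mode=pad_mode, rng=rng)
        self.norm1 = InstanceNorm2d(channels)
        self.conv2 = Conv2d(channels, channels, 3, padding=1,
                            pad_mode=pad_mode, rng=rng)
        self.norm2 = InstanceNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        return x + h


def bilinear_matrix(out_size: int, in_size: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (half-pixel centers)."""
    mat = np.zeros((out_size, in_size))
    if in_size == 1:
        mat[:, 0] = 1.0
        return mat
    src = (np.arange(out_size) + 0.5) * in_size / out_size - 0.5
    src = np.clip(src, 0, in_size - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, in_size - 1)
    frac = src - lo
    mat[np.arange(out_size), lo] += 1.0 - frac
    mat[np.arange(out_size), hi] += frac
    return mat


class Upsample2d(Module):
    """Fixed bilinear upsampling by an integer factor (no parameters)."""

    def __init__(self, factor: int):
        self.factor = factor
        self._cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        key = (h, w)
        if key not in self._cache:
            self._cache[key] = (bilinear_matrix(h * self.factor, h),
                                bilinear_matrix(w * self.factor, w))
        mat_h, mat_w = self._cache[key]
        return interp2d(x, mat_h, mat_w)
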