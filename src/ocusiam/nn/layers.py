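"""Neural-network building blocks on top of the autograd engine.

Layers follow the familiar module pattern: a :class:`Module` owns
:class:`Parameter` tensors (discoverable recursively), supports train/eval
modes, and is called on a :class:`~ocusiam.nn.autograd.Tensor`.  Convolution
is im2col + matmul built from the ``take_flat`` gather primitive, so its
backward pass falls out of the tape.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Linear",
    "Conv2d",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "BatchNorm2d",
    "ReLU",
    "Flatten",
]


class Parameter(Tensor):
    """A tensor registered as trainable state of a module."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, call protocol."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    # checkpoint plumbing -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for m_idx, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{m_idx}.running_mean"] = m.running_mean.copy()
                state[f"__bn{m_idx}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            if name not in state:
                raise KeyError(f"missing parameter in checkpoint: {name}")
            if state[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()
        for m_idx, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = state[f"__bn{m_idx}.running_mean"].copy()
                m.running_var = state[f"__bn{m_idx}.running_var"].copy()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], int(np.prod(x.shape[1:])))


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, in_features, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight.transpose() + self.bias


def _patch_indices(n: int, c: int, h: int, w: int, kh: int, kw: int, stride: int):
    """Flat gather indices of shape (n, c*kh*kw, oh*ow) into an (n,c,h,w) array."""
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    chan = np.repeat(np.arange(c), kh * kw)[:, None]
    i0 = np.tile(np.repeat(np.arange(kh), kw), c)[:, None]
    j0 = np.tile(np.arange(kw), kh * c)[:, None]
    oi = stride * np.repeat(np.arange(oh), ow)[None, :]
    oj = stride * np.tile(np.arange(ow), oh)[None, :]
    idx = (chan * h + i0 + oi) * w + (j0 + oj)
    batch = (np.arange(n) * c * h * w)[:, None, None]
    return batch + idx[None], oh, ow


class Conv2d(Module):
    """2-D convolution (cross-correlation) with symmetric zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        k = in_channels * kernel_size * kernel_size
        self.weight = Parameter(_kaiming(rng, k, (out_channels, k)))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"conv expects {self.in_channels} input channels, got {c}"
            )
        xp = x.pad2d(self.padding)
        hp, wp = h + 2 * self.padding, w + 2 * self.padding
        idx, oh, ow = _patch_indices(
            n, c, hp, wp, self.kernel_size, self.kernel_size, self.stride
        )
        cols = xp.take_flat(idx)  # (n, c*k*k, oh*ow)
        flat = cols.transpose(0, 2, 1).reshape(n * oh * ow, -1)
        out = flat @ self.weight.transpose() + self.bias
        return out.reshape(n, oh, ow, self.out_channels).transpose(0, 3, 1, 2)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int | None = None):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride if stride is not None else kernel_size

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        idx, oh, ow = _patch_indices(
            n, c, h, w, self.kernel_size, self.kernel_size, self.stride
        )
        cols = x.take_flat(idx)  # (n, c*k*k, oh*ow)
        k2 = self.kernel_size * self.kernel_size
        return cols.reshape(n, c, k2, oh * ow).max(axis=2).reshape(n, c, oh, ow)


class GlobalAvgPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics for eval mode."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones((1, num_features, 1, 1)))
        self.beta = Parameter(np.zeros((1, num_features, 1, 1)))
        self.running_mean = np.zeros((1, num_features, 1, 1))
        self.running_var = np.ones((1, num_features, 1, 1))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data
            )
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return self.gamma * xhat + self.beta
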