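"""Channel and spatial attention operators and their sequential composition.

The channel operator squeezes the feature map ``F`` (C x H x W) to two
C-vectors by spatial average- and max-pooling, pushes both through one shared
two-layer perceptron, adds the results and applies a sigmoid:

    M_c(F) = sigmoid(MLP(AvgPool(F)) + MLP(MaxPool(F)))        (C x 1 x 1)

The spatial operator pools along the channel axis instead, concatenates the
two planes, and convolves them with a single odd-sized kernel:

    M_s(F) = sigmoid(conv_kxk(concat(AvgPool_c(F), MaxPool_c(F))))  (1 x H x W)

Applied sequentially — channel first, then spatial — each map multiplies the
feature it was computed from, so attention only rescales activations: the
output never exceeds the input in magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, Linear, Module, Tensor, concatenate

__all__ = [
    "AttentionConfig",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "export_attention_overlay",
]


@dataclass(frozen=True)
class AttentionConfig:
    """Configuration of the attention block.

    Parameters
    ----------
    reduction :
        MLP bottleneck ratio r; hidden width is ``max(C // r, 1)``.
    spatial_kernel :
        Odd kernel size of the spatial-attention convolution (default 7).
    channel, spatial :
        Enable flags; a disabled component is the identity.
    """

    reduction: int = 16
    spatial_kernel: int = 7
    channel: bool = True
    spatial: bool = True

    def __post_init__(self):
        if self.spatial_kernel % 2 == 0 or self.spatial_kernel < 1:
            raise ValueError(
                f"spatial attention kernel must be odd and positive, got "
                f"{self.spatial_kernel}"
            )
        if self.reduction < 1:
            raise ValueError("reduction ratio must be >= 1")

    @property
    def tag(self) -> str:
        return {
            (False, False): "none",
            (True, False): "channel",
            (False, True): "spatial",
            (True, True): "both",
        }[(self.channel, self.spatial)]


class ChannelAttention(Module):
    """Per-channel gating weights from pooled spatial descriptors."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(self.fc1(v).relu())

    def forward(self, f: Tensor) -> Tensor:
        n, c, h, w = f.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        flat = f.reshape(n, c, h * w)
        avg = flat.mean(axis=2)       # (n, c)
        mx = flat.max(axis=2)         # (n, c)
        m = (self._mlp(avg) + self._mlp(mx)).sigmoid()
        return m.reshape(n, c, 1, 1)


class SpatialAttention(Module):
    """Per-location gating map from channel-pooled descriptor planes."""

    def __init__(self, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError(f"spatial kernel must be odd, got {kernel_size}")
        self.conv = Conv2d(2, 1, kernel_size, rng, padding=(kernel_size - 1) // 2)

    def forward(self, f: Tensor) -> Tensor:
        avg = f.mean(axis=1, keepdims=True)                 # (n,1,h,w)
        mx = f.max(axis=1, keepdims=True)                   # (n,1,h,w)
        return self.conv(concatenate([avg, mx], axis=1)).sigmoid()


class CBAM(Module):
    """Sequential channel-then-spatial attention; refines ``F`` in place:

    ``F' = M_c(F) * F``; ``F'' = M_s(F') * F'``.
    """

    def __init__(self, channels: int, config: AttentionConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.channel_attention = (
            ChannelAttention(channels, config.reduction, rng) if config.channel else None
        )
        self.spatial_attention = (
            SpatialAttention(config.spatial_kernel, rng) if config.spatial else None
        )
        self._last_spatial_map: np.ndarray | None = None

    def forward(self, f: Tensor) -> Tensor:
        if self.channel_attention is not None:
            f = self.channel_attention(f) * f
        if self.spatial_attention is not None:
            m = self.spatial_attention(f)
            self._last_spatial_map = m.data.copy()
            f = m * f
        return f

    @property
    def last_spatial_map(self) -> np.ndarray | None:
        """1 x H x W map(s) from the most recent forward pass, for overlays."""
        return self._last_spatial_map


def export_attention_overlay(
    image: np.ndarray, spatial_map: np.ndarray, path, alpha: float = 0.5
) -> None:
    """Write a false-color overlay of a spatial-attention map onto an image.

    Parameters
    ----------
    image :
        (C, H, W) preprocessed image; rescaled to [0,1] for display.
    spatial_map :
        (1, h, w) or (h, w) attention weights in (0,1); bilinearly upsampled
        to the image size.
    path :
        Output PNG path.
    """
    from PIL import Image
    from matplotlib import colormaps
    from skimage.transform import resize

    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3:
        raise ValueError("image must be (C, H, W)")
    gray = img.mean(axis=0)
    lo, hi = gray.min(), gray.max()
    gray = (gray - lo) / (hi - lo) if hi > lo else np.zeros_like(gray)

    m = np.asarray(spatial_map, dtype=np.float64)
    if m.ndim == 3:
        m = m[0]
    m = resize(m, gray.shape, order=1, anti_aliasing=False, preserve_range=True)

    heat = colormaps["jet"](m)[..., :3]
    base = np.stack([gray] * 3, axis=-1)
    blended = (1 - alpha) * base + alpha * heat
    out = (np.clip(blended, 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(out).save(path, format="PNG")
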