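"""Siamese branch networks: convolutional stages, attention block, FC head.

A siamese model is ONE branch network applied to both members of an image
pair — weight sharing is exact because there is a single parameter set, not
a synchronized copy.  Each branch is: convolutional feature stages (one of
four architectures), a channel+spatial attention block on the final feature
map, then a fully-connected head ending in the embedding layer.  Distances
between embeddings drive both the contrastive objective and the KNN readout.

Architectures:

``vgg16``
    13 conv layers of 3x3 kernels in five stages (64,64 / 128,128 /
    256x3 / 512x3 / 512x3), 2x2 max-pool after each stage, attention,
    head FC(4096) -> FC(512) -> FC(100).
``alexnet``
    Conv 64@11x11/4, pool 3x3/2, conv 192@5x5, pool, conv 384/256/256@3x3,
    pool, attention, same head widths as vgg16.
``resnet18``
    7x7/2 stem with 3x3/2 pool, four stages of two basic residual blocks
    (64,128,256,512; 1x1 downsample convs where the width changes), attention,
    global average pool, head FC(512) -> FC(100).
``tiny``
    A desk-scale branch (3 conv stages of width 8/16/32 on 64x64 inputs,
    head FC(128) -> FC(32) -> FC(16)) so the full pipeline trains on one CPU
    in seconds.  It is an engineering configuration, not a claim about any
    clinical result.

Pretrained ImageNet weights are consumed, never produced, and require a local
weight file; without one, ``pretrained=True`` raises with a pointer to the
seeded random-initialization mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .attention import CBAM, AttentionConfig
from .imaging import PreprocessedImage
from .nn import (
    BatchNorm2d,
    Conv2d,
    Flatten,
    GlobalAvgPool2d,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
    Tensor,
)

__all__ = [
    "BranchConfig",
    "BranchNetwork",
    "PretrainedWeightsUnavailableError",
    "build_branch",
    "embed",
    "forward_pair",
    "save_checkpoint",
    "load_checkpoint",
]

ARCHITECTURES = ("vgg16", "alexnet", "resnet18", "tiny")


class PretrainedWeightsUnavailableError(RuntimeError):
    pass


@dataclass(frozen=True)
class BranchConfig:
    architecture: str = "vgg16"
    pretrained: bool = False
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    embedding_dim: int = 100
    input_size: int = 224
    input_channels: int = 3

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                f"choose from {ARCHITECTURES}"
            )
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if self.architecture == "tiny" and self.pretrained:
            raise ValueError("the tiny architecture has no pretrained weights")

    @classmethod
    def tiny(cls, attention: AttentionConfig | None = None) -> "BranchConfig":
        """The desk-scale configuration: 64x64 input, 16-d embedding."""
        return cls(
            architecture="tiny",
            attention=attention or AttentionConfig(),
            embedding_dim=16,
            input_size=64,
        )

    def to_dict(self) -> dict:
        return {
            "architecture": self.architecture,
            "pretrained": self.pretrained,
            "attention": vars(self.attention),
            "embedding_dim": self.embedding_dim,
            "input_size": self.input_size,
            "input_channels": self.input_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BranchConfig":
        d = dict(d)
        d["attention"] = AttentionConfig(**d["attention"])
        return cls(**d)


class _BasicBlock(Module):
    """Residual block: two 3x3 convs with batch norm; optional 1x1 downsample."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, rng, stride=stride, padding=1)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng, padding=1)
        self.bn2 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down_conv = Conv2d(cin, cout, 1, rng, stride=stride)
            self.down_bn = BatchNorm2d(cout)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        identity = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (out + identity).relu()


def _vgg16_features(cin: int, rng) -> tuple[Sequential, int]:
    plan = [(64, 2), (128, 2), (256, 3), (512, 3), (512, 3)]
    layers: list[Module] = []
    c = cin
    for width, reps in plan:
        for _ in range(reps):
            layers += [Conv2d(c, width, 3, rng, padding=1), ReLU()]
            c = width
        layers.append(MaxPool2d(2))
    return Sequential(*layers), c


def _alexnet_features(cin: int, rng) -> tuple[Sequential, int]:
    layers = [
        Conv2d(cin, 64, 11, rng, stride=4, padding=2), ReLU(),
        MaxPool2d(3, stride=2),
        Conv2d(64, 192, 5, rng, padding=2), ReLU(),
        MaxPool2d(3, stride=2),
        Conv2d(192, 384, 3, rng, padding=1), ReLU(),
        Conv2d(384, 256, 3, rng, padding=1), ReLU(),
        Conv2d(256, 256, 3, rng, padding=1), ReLU(),
        MaxPool2d(3, stride=2),
    ]
    return Sequential(*layers), 256


def _resnet18_features(cin: int, rng) -> tuple[Sequential, int]:
    layers: list[Module] = [
        Conv2d(cin, 64, 7, rng, stride=2, padding=3),
        BatchNorm2d(64), ReLU(),
        MaxPool2d(3, stride=2),
    ]
    c = 64
    for width, stride in [(64, 1), (128, 2), (256, 2), (512, 2)]:
        layers.append(_BasicBlock(c, width, stride, rng))
        layers.append(_BasicBlock(width, width, 1, rng))
        c = width
    return Sequential(*layers), c


def _tiny_features(cin: int, rng) -> tuple[Sequential, int]:
    layers: list[Module] = []
    c = cin
    for width in (8, 16, 32):
        layers += [Conv2d(c, width, 3, rng, padding=1), ReLU(), MaxPool2d(2)]
        c = width
    return Sequential(*layers), c


_FEATURES = {
    "vgg16": _vgg16_features,
    "alexnet": _alexnet_features,
    "resnet18": _resnet18_features,
    "tiny": _tiny_features,
}

_HEAD_WIDTHS = {
    "vgg16": (4096, 512),
    "alexnet": (4096, 512),
    "resnet18": (512,),
    "tiny": (128, 32),
}


class BranchNetwork(Module):
    """One shared siamese branch: features -> attention -> FC head."""

    def __init__(self, config: BranchConfig, seed: int):
        super().__init__()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.features, channels = _FEATURES[config.architecture](
            config.input_channels, rng
        )
        self.attention = CBAM(channels, config.attention, rng)
        self.feature_channels = channels

        # probe spatial size with a dry forward pass
        probe = Tensor(
            np.zeros((1, config.input_channels, config.input_size, config.input_size))
        )
        was_training = self.training
        self.eval()
        feat = self.features(probe)
        self._feature_hw = feat.shape[2:]
        if config.architecture == "resnet18":
            flat_dim = channels
            pre_head: list[Module] = [GlobalAvgPool2d()]
        else:
            flat_dim = channels * feat.shape[2] * feat.shape[3]
            pre_head = [Flatten()]
        widths = _HEAD_WIDTHS[config.architecture]
        layers: list[Module] = list(pre_head)
        d = flat_dim
        for wdt in widths:
            layers += [Linear(d, wdt, rng), ReLU()]
            d = wdt
        layers.append(Linear(d, config.embedding_dim, rng))
        self.head = Sequential(*layers)
        if was_training:
            self.train()

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.config.input_channels or x.shape[2:] != (
            self.config.input_size,
            self.config.input_size,
        ):
            raise ValueError(
                f"expected input {self.config.input_channels}x"
                f"{self.config.input_size}x{self.config.input_size}, "
                f"got {x.shape[1:]}"
            )
        return self.head(self.attention(self.features(x)))

    # convenience ndarray interfaces ------------------------------------
    def embed_batch(self, images: np.ndarray) -> np.ndarray:
        """Embed an (N, C, H, W) stack in evaluation mode."""
        was_training = self.training
        self.eval()
        out = self.forward(Tensor(np.asarray(images, dtype=np.float64))).data
        if was_training:
            self.train()
        return out

    def spatial_attention_map(self, images: np.ndarray) -> np.ndarray | None:
        """Run a forward pass and return the spatial-attention map(s)."""
        self.embed_batch(images)
        return self.attention.last_spatial_map


def build_branch(config: BranchConfig, seed: int = 0) -> BranchNetwork:
    """Construct a branch network with seeded initialization.

    ``pretrained=True`` requires locally available weights; none ship with
    this package, so the call fails with an explicit pointer to random
    initialization.
    """
    if config.pretrained:
        raise PretrainedWeightsUnavailableError(
            f"no local pretrained weights available for {config.architecture!r}; "
            "rebuild with pretrained=False for seeded random initialization"
        )
    return BranchNetwork(config, seed)


def embed(net: BranchNetwork, img: PreprocessedImage) -> np.ndarray:
    """Embedding vector of one preprocessed image (evaluation mode)."""
    return net.embed_batch(img.pixels[None])[0]


def forward_pair(
    net: BranchNetwork, a: PreprocessedImage, b: PreprocessedImage
) -> tuple[np.ndarray, np.ndarray, float]:
    """Embed both images through the shared branch; return (e_a, e_b, d)."""
    out = net.embed_batch(np.stack([a.pixels, b.pixels]))
    d = float(np.linalg.norm(out[0] - out[1]))
    return out[0], out[1], d


def save_checkpoint(net: BranchNetwork, path: str | Path, extra: dict | None = None):
    """Write parameters (npz) plus a JSON sidecar with config and provenance."""
    path = Path(path)
    if not path.name.endswith(".npz"):
        path = Path(str(path) + ".npz")
    np.savez(path, **net.state_dict())
    sidecar = {
        "config": net.config.to_dict(),
        "seed": net.seed,
        **(extra or {}),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path: str | Path) -> BranchNetwork:
    path = Path(path)
    if not path.name.endswith(".npz"):
        path = Path(str(path) + ".npz")
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    config = BranchConfig.from_dict(sidecar["config"])
    net = BranchNetwork(config, seed=sidecar.get("seed", 0))
    with np.load(path) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net
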