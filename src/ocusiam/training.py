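"""Pair construction, contrastive loss, and the siamese training loop.

Training operates on randomly sampled image pairs.  A pair is *positive*
(match label y = 1) when both images carry the same class label and
*negative* (y = 0) otherwise.  The objective over a batch of N pairs with
embedding distances d is

    L = 1/(2N) * sum_n [ y * d^2 + (1 - y) * max(margin - d, 0)^2 ]

which pulls same-class embeddings together and pushes different-class
embeddings beyond the margin.  Default hyperparameters are the study
conditions this package targets: Adam at learning rate 1e-5, batch size 50
pairs, 50 epochs.  The margin (not stated in those conditions) defaults
to 1.0, the common choice for unnormalized embeddings.

Every stochastic step (pair sampling, initialization) is a pure function of
its seed, so run-twice reproducibility is a testable contract.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .backbone import BranchNetwork
from .nn import Adam, Tensor

__all__ = [
    "ImagePair",
    "LossConfig",
    "TrainConfig",
    "sample_pairs",
    "contrastive_loss",
    "train_model",
]


@dataclass(frozen=True)
class ImagePair:
    """Two manifest indices plus the match label y (1 = same class)."""

    first: int
    second: int
    y: int

    def __post_init__(self):
        if self.first == self.second:
            raise ValueError("a pair must reference two distinct images")
        if self.y not in (0, 1):
            raise ValueError("match label y must be 0 or 1")


@dataclass(frozen=True)
class LossConfig:
    margin: float = 1.0

    def __post_init__(self):
        if self.margin <= 0:
            raise ValueError("margin must be positive")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    batch_size: int = 50
    epochs: int = 50
    pairs_per_epoch: int | None = None  # None -> training-set size
    positive_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid training configuration")
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ValueError("positive_fraction must be in [0, 1]")


def _derived_seed(base: int, *parts) -> int:
    h = hashlib.sha256(":".join(map(str, (base, *parts))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def sample_pairs(
    labels: Sequence[str],
    n_pairs: int,
    positive_fraction: float = 0.5,
    seed: int = 0,
) -> list[ImagePair]:
    """Draw labeled index pairs: exactly round(f * n) positive, rest negative."""
    if not (0.0 <= positive_fraction <= 1.0):
        raise ValueError(f"positive_fraction must be in [0,1], got {positive_fraction}")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("pair sampling needs both classes present")
    by_class = {c: np.flatnonzero(labels == c) for c in classes}
    n_pos = int(round(positive_fraction * n_pairs))
    if n_pos > 0 and all(len(v) < 2 for v in by_class.values()):
        raise ValueError("positive pairs requested but no class has 2 images")
    rng = np.random.default_rng(seed)
    pairs: list[ImagePair] = []
    eligible = [c for c in classes if len(by_class[c]) >= 2]
    for _ in range(n_pos):
        c = eligible[rng.integers(len(eligible))]
        i, j = rng.choice(by_class[c], size=2, replace=False)
        pairs.append(ImagePair(int(i), int(j), 1))
    for _ in range(n_pairs - n_pos):
        ca, cb = rng.choice(len(classes), size=2, replace=False)
        i = rng.choice(by_class[classes[ca]])
        j = rng.choice(by_class[classes[cb]])
        pairs.append(ImagePair(int(i), int(j), 0))
    return pairs


def contrastive_loss(
    y: Sequence[int], distances: Sequence[float], config: LossConfig | None = None
) -> float:
    """Mean contrastive loss over a batch, from match labels and distances."""
    config = config or LossConfig()
    y = np.asarray(y, dtype=np.float64)
    d = np.asarray(distances, dtype=np.float64)
    if y.shape != d.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {d.shape} distances")
    if y.size == 0:
        raise ValueError("empty batch")
    if (d < 0).any():
        raise ValueError("distances must be nonnegative")
    hinge = np.maximum(config.margin - d, 0.0)
    return float((y * d**2 + (1 - y) * hinge**2).sum() / (2 * y.size))


def pair_loss_tensor(
    e1: Tensor, e2: Tensor, y: np.ndarray, margin: float
) -> Tensor:
    """Differentiable contrastive loss from two embedding batches."""
    diff = e1 - e2
    d2 = (diff * diff).sum(axis=1)
    d = (d2 + 1e-12).sqrt()
    yv = Tensor(np.asarray(y, dtype=np.float64))
    pos = yv * d2
    neg = (1.0 - yv) * ((margin - d).clamp_min(0.0) ** 2)
    return (pos + neg).sum() * (1.0 / (2 * len(y)))


def train_model(
    net: BranchNetwork,
    images: np.ndarray,
    labels: Sequence[str],
    tcfg: TrainConfig | None = None,
    lcfg: LossConfig | None = None,
) -> list[float]:
    """Train the shared branch on pairs drawn from (images, labels).

    Parameters
    ----------
    images :
        (N, C, H, W) preprocessed stack aligned with ``labels``.
    labels :
        class label per image.

    Returns the per-epoch mean losses.  Zero epochs is a no-op with empty
    history.  The run is a pure function of the configurations' seeds.
    """
    tcfg = tcfg or TrainConfig()
    lcfg = lcfg or LossConfig()
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 4 or images.shape[0] != len(labels):
        raise ValueError("images must be (N, C, H, W) aligned with labels")
    n_pairs = tcfg.pairs_per_epoch or images.shape[0]
    optimizer = Adam(net.parameters(), lr=tcfg.learning_rate)
    net.train()
    history: list[float] = []
    for epoch in range(tcfg.epochs):
        pairs = sample_pairs(
            labels, n_pairs, tcfg.positive_fraction,
            seed=_derived_seed(tcfg.seed, "pairs", epoch),
        )
        epoch_loss, seen = 0.0, 0
        for start in range(0, len(pairs), tcfg.batch_size):
            batch = pairs[start : start + tcfg.batch_size]
            a = images[[p.first for p in batch]]
            b = images[[p.second for p in batch]]
            yb = np.array([p.y for p in batch], dtype=np.float64)
            e1 = net(Tensor(a))
            e2 = net(Tensor(b))
            loss = pair_loss_tensor(e1, e2, yb, lcfg.margin)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // tcfg.batch_size}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += value * len(batch)
            seen += len(batch)
        history.append(epoch_loss / seen)
    net.eval()
    return history
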