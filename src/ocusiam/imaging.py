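"""Image loading, preprocessing and dataset-manifest management.

The preprocessing contract, in fixed order: crop the fundus window out of the
raw B-scan, resize to the network's square input, then normalize each channel

    xn_i = (x_i - x_mean) / x_std

with the fixed shortcut mean = std = 0.5 per channel by default (mapping
[0,1] intensities onto [-1,1]), or statistics estimated from the image when
requested.  The crop window shipped as default is x in [100,400), y in
[50,300) in top-left-origin pixel coordinates — a 300 x 250 window that keeps
the fundus and discards the instrument margins.

Manifests are plain CSV (``path,label`` header) or an equivalent JSON list;
splits are stratified 7:3 by default and reproducible under a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage as ndi
from skimage.transform import resize as _sk_resize

__all__ = [
    "RawImage",
    "CropSpec",
    "DEFAULT_CROP",
    "NormalizationSpec",
    "PreprocessedImage",
    "PreprocessConfig",
    "DatasetManifest",
    "AugmentSpec",
    "load_image",
    "crop_fundus",
    "resize_to_input",
    "normalize_channels",
    "preprocess_image",
    "stratified_split",
    "traditional_augment",
]


@dataclass
class RawImage:
    """Decoded image: (H, W, C) float64 intensities in [0, 1]."""

    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3 or px.shape[2] not in (1, 3):
            raise ValueError(f"expected HxWx{{1,3}} pixels, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if not np.isfinite(px).all():
            raise ValueError("image contains non-finite values")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]

    def to_rgb(self) -> "RawImage":
        if self.channels == 3:
            return self
        return RawImage(np.repeat(self.pixels, 3, axis=2), self.source_path)


@dataclass(frozen=True)
class CropSpec:
    """Half-open crop rectangle [x1,x2) x [y1,y2), origin top-left."""

    x1: int
    y1: int
    x2: int
    y2: int

    def __post_init__(self):
        if not (0 <= self.x1 < self.x2 and 0 <= self.y1 < self.y2):
            raise ValueError(
                f"invalid crop rectangle x[{self.x1},{self.x2}) y[{self.y1},{self.y2})"
            )

    @property
    def width(self) -> int:
        return self.x2 - self.x1

    @property
    def height(self) -> int:
        return self.y2 - self.y1


#: The shipped fundus window: 300 px wide, 250 px tall.
DEFAULT_CROP = CropSpec(x1=100, y1=50, x2=400, y2=300)


@dataclass(frozen=True)
class NormalizationSpec:
    """Per-channel standardization: fixed constants or image-estimated."""

    mean: tuple[float, ...] = (0.5, 0.5, 0.5)
    std: tuple[float, ...] = (0.5, 0.5, 0.5)
    mode: str = "fixed"  # or "estimated"

    def __post_init__(self):
        if self.mode not in ("fixed", "estimated"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        if any(s <= 0 for s in self.std):
            raise ValueError("std must be strictly positive per channel")


@dataclass
class PreprocessedImage:
    """Normalized (C, side, side) pixel grid ready for the network."""

    pixels: np.ndarray  # (C, H, W)
    label: str | None = None
    source_path: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3:
            raise ValueError("preprocessed pixels must be (C, H, W)")
        if not np.isfinite(px).all():
            raise ValueError("preprocessed image contains non-finite values")
        self.pixels = px


@dataclass(frozen=True)
class PreprocessConfig:
    """End-to-end preprocessing: crop -> resize -> normalize."""

    crop: CropSpec | None = DEFAULT_CROP
    side: int = 224
    normalization: NormalizationSpec = field(default_factory=NormalizationSpec)
    to_rgb: bool = True


def load_image(path: str | Path, to_rgb: bool = False) -> RawImage:
    """Decode a PNG/JPEG into [0,1] float intensities.

    Grayscale stays single-channel unless ``to_rgb`` replicates it to 3.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode not in ("L", "RGB"):
                im = im.convert("RGB" if len(im.getbands()) >= 3 else "L")
            arr = np.asarray(im, dtype=np.float64) / 255.0
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"cannot decode image file {path}: {exc}") from exc
    img = RawImage(arr, source_path=str(path))
    return img.to_rgb() if to_rgb else img


def crop_fundus(img: RawImage, spec: CropSpec) -> RawImage:
    """Extract the half-open window [x1,x2) x [y1,y2)."""
    if spec.x2 > img.width or spec.y2 > img.height:
        raise ValueError(
            f"crop x[{spec.x1},{spec.x2}) y[{spec.y1},{spec.y2}) exceeds "
            f"image bounds {img.width}x{img.height}"
        )
    return RawImage(
        img.pixels[spec.y1 : spec.y2, spec.x1 : spec.x2].copy(), img.source_path
    )


def resize_to_input(img: RawImage, side: int = 224) -> RawImage:
    """Bilinear resize to side x side, clamped to [0,1]."""
    if side < 1:
        raise ValueError(f"target side must be >= 1, got {side}")
    if img.height == side and img.width == side:
        return RawImage(img.pixels.copy(), img.source_path)
    out = _sk_resize(
        img.pixels, (side, side, img.channels), order=1,
        anti_aliasing=False, preserve_range=True,
    )
    return RawImage(np.clip(out, 0.0, 1.0), img.source_path)


def normalize_channels(
    img: RawImage, spec: NormalizationSpec | None = None, label: str | None = None
) -> PreprocessedImage:
    """Channel-wise standardization (x - mean) / std -> (C, H, W) grid."""
    spec = spec or NormalizationSpec()
    px = img.pixels  # (H, W, C)
    c = px.shape[2]
    if spec.mode == "estimated":
        mean = px.reshape(-1, c).mean(axis=0)
        std = px.reshape(-1, c).std(axis=0)
        if np.any(std == 0):
            raise ValueError(
                "constant channel: cannot estimate std for normalization"
            )
    else:
        mean = np.asarray(spec.mean[:c] if len(spec.mean) >= c else spec.mean * c)
        std = np.asarray(spec.std[:c] if len(spec.std) >= c else spec.std * c)
    out = (px - mean) / std
    return PreprocessedImage(
        np.moveaxis(out, 2, 0), label=label, source_path=img.source_path
    )


def preprocess_image(
    img: RawImage, config: PreprocessConfig, label: str | None = None
) -> PreprocessedImage:
    """Pipeline crop -> resize -> normalize (order fixed by contract)."""
    if config.to_rgb:
        img = img.to_rgb()
    if config.crop is not None:
        img = crop_fundus(img, config.crop)
    img = resize_to_input(img, config.side)
    return normalize_channels(img, config.normalization, label=label)


# ---------------------------------------------------------------------------
# manifests and splitting


@dataclass
class DatasetManifest:
    """Two-class (path, label) table with a split tag."""

    records: pd.DataFrame  # columns: path, label
    split: str = "unsplit"

    def __post_init__(self):
        df = pd.DataFrame(self.records, columns=["path", "label"]).reset_index(
            drop=True
        )
        if df["path"].duplicated().any():
            dup = df.loc[df["path"].duplicated(), "path"].iloc[0]
            raise ValueError(f"duplicate path in manifest: {dup}")
        self.records = df

    @property
    def classes(self) -> list[str]:
        return sorted(self.records["label"].unique().tolist())

    def __len__(self) -> int:
        return len(self.records)

    def class_counts(self) -> dict[str, int]:
        return self.records["label"].value_counts().to_dict()

    @classmethod
    def from_csv(cls, path: str | Path, split: str = "unsplit") -> "DatasetManifest":
        df = pd.read_csv(path, dtype=str)
        if list(df.columns[:2]) != ["path", "label"]:
            raise ValueError(f"manifest {path} must have header 'path,label'")
        return cls(df[["path", "label"]], split=split)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_json(cls, path: str | Path, split: str = "unsplit") -> "DatasetManifest":
        entries = json.loads(Path(path).read_text())
        return cls(pd.DataFrame(entries, columns=["path", "label"]), split=split)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.records.to_dict(orient="records"), indent=1)
        )


def stratified_split(
    manifest: DatasetManifest,
    train_fraction: float = 0.7,
    seed: int = 0,
    allow_empty_test: bool = False,
) -> tuple[DatasetManifest, DatasetManifest]:
    """Per-class split: floor(train_fraction * n_c) to train, rest to test.

    Deterministic under ``seed``; classes with fewer than 2 images are
    rejected.
    """
    if not (0.0 < train_fraction <= 1.0):
        raise ValueError(f"train_fraction must be in (0, 1], got {train_fraction}")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    df = manifest.records
    for label in manifest.classes:
        sub = df[df["label"] == label].reset_index(drop=True)
        if len(sub) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 images")
        n_train = int(np.floor(train_fraction * len(sub)))
        order = rng.permutation(len(sub))
        train_parts.append(sub.iloc[order[:n_train]])
        test_parts.append(sub.iloc[order[n_train:]])
    train_df = pd.concat(train_parts).reset_index(drop=True)
    test_df = pd.concat(test_parts).reset_index(drop=True)
    if len(test_df) == 0 and not allow_empty_test:
        raise ValueError(
            "split produced an empty test set; pass allow_empty_test=True "
            "if intentional"
        )
    return (
        DatasetManifest(train_df, split="train"),
        DatasetManifest(test_df, split="test"),
    )


# ---------------------------------------------------------------------------
# traditional augmentation


@dataclass(frozen=True)
class AugmentSpec:
    """Traditional augmentation: which transforms run and their ranges.

    Transforms apply in the fixed order random-crop -> rotation ->
    vertical-flip -> horizontal-flip -> color-jitter.  Flips are
    deterministic when enabled; crop geometry, rotation angle and jitter
    factors are drawn from the seeded generator.
    """

    random_crop: bool = False
    crop_scale: tuple[float, float] = (0.7, 1.0)
    rotation: bool = False
    max_degrees: float = 15.0
    vertical_flip: bool = False
    horizontal_flip: bool = False
    color_jitter: bool = False
    brightness: float = 0.2
    contrast: float = 0.2

    def __post_init__(self):
        if not any(
            (
                self.random_crop,
                self.rotation,
                self.vertical_flip,
                self.horizontal_flip,
                self.color_jitter,
            )
        ):
            raise ValueError("at least one augmentation transform must be enabled")


def traditional_augment(img: RawImage, spec: AugmentSpec, seed: int) -> RawImage:
    """Apply the enabled transforms in fixed order; pure in (img, spec, seed)."""
    rng = np.random.default_rng(seed)
    px = img.pixels.copy()
    h, w, _ = px.shape
    if spec.random_crop:
        scale = rng.uniform(*spec.crop_scale)
        ch, cw = max(1, int(round(h * scale))), max(1, int(round(w * scale)))
        y0 = rng.integers(0, h - ch + 1)
        x0 = rng.integers(0, w - cw + 1)
        sub = px[y0 : y0 + ch, x0 : x0 + cw]
        px = np.clip(
            _sk_resize(sub, (h, w, px.shape[2]), order=1, anti_aliasing=False,
                       preserve_range=True),
            0.0, 1.0,
        )
    if spec.rotation:
        angle = rng.uniform(-spec.max_degrees, spec.max_degrees)
        if angle != 0.0:
            px = np.clip(
                ndi.rotate(px, angle, axes=(0, 1), reshape=False, order=1,
                           mode="constant", cval=0.0),
                0.0, 1.0,
            )
    if spec.vertical_flip:
        px = px[::-1].copy()
    if spec.horizontal_flip:
        px = px[:, ::-1].copy()
    if spec.color_jitter:
        b = rng.uniform(-spec.brightness, spec.brightness)
        c = 1.0 + rng.uniform(-spec.contrast, spec.contrast)
        mean = px.mean()
        px = np.clip((px - mean) * c + mean + b, 0.0, 1.0)
    return RawImage(px, img.source_path)
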