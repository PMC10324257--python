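"""Synthetic two-class ocular-ultrasound-like image generator.

Real fundus B-scans of the two conditions differ in lesion morphology:
vitreous opacities (VO) echo as *discrete* bright spots floating in the
vitreous, while a posterior vitreous detachment (PVD) echoes as a
*continuous* bright membrane arcing above the retina.  The generator renders
exactly that contrast on a dark background containing a brighter elliptical
fundus region:

* ``vo``-like images: a configurable number of disjoint Gaussian-profile
  bright blobs inside the ellipse;
* ``pvd``-like images: one thickened curvilinear arc following the posterior
  ellipse boundary, optionally only partially rendered (``continuity``).

Multiplicative speckle noise is applied last.  With noise 0 and the default
well-separated intensity regimes, counting bright connected components
separates the classes perfectly, so the learning problem posed to the
pipeline is solvable by construction.  No claim of physical realism (no
point-spread function or attenuation) is made.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .imaging import DatasetManifest, RawImage

__all__ = ["LesionParams", "SyntheticSpec", "generate_image", "generate_dataset",
           "CLASS_VO", "CLASS_PVD"]

CLASS_VO = "VO"
CLASS_PVD = "PVD"


@dataclass(frozen=True)
class LesionParams:
    """Morphology of the lesions rendered for one class."""

    # VO-like: discrete bright foci
    spot_count: int = 4
    spot_radius: tuple[float, float] = (6.0, 12.0)
    spot_intensity: tuple[float, float] = (0.75, 0.95)
    # PVD-like: continuous bright arc
    arc_amplitude: float = 0.75   # fraction of the ellipse semi-axes traced
    arc_thickness: float = 6.0    # half-thickness in pixels
    arc_intensity: float = 0.85
    continuity: float = 1.0       # fraction of the arc actually rendered

    def __post_init__(self):
        if self.spot_count < 1:
            raise ValueError("spot_count must be >= 1")
        if self.spot_radius[0] < 1:
            raise ValueError("spot radius must be >= 1 pixel")
        if not (0.0 < self.continuity <= 1.0):
            raise ValueError("continuity must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic dataset regime.

    Defaults emulate the study regime this package targets: 220 images per
    class, 512 x 512 frames on which the shipped fundus crop window applies
    unchanged, and mild speckle.
    """

    size: int = 512
    ellipse_center: tuple[float, float] = (0.5, 0.52)   # fractional (x, y)
    ellipse_axes: tuple[float, float] = (0.34, 0.30)    # fractional semi-axes
    background_level: float = 0.05
    fundus_level: float = 0.25
    noise_level: float = 0.08
    lesions: LesionParams = field(default_factory=LesionParams)
    n_per_class: int = 220
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.noise_level < 0:
            raise ValueError("noise level must be >= 0")
        if not self.background_level < self.fundus_level < 1.0:
            raise ValueError("need background_level < fundus_level < 1")

    @classmethod
    def for_size(cls, size: int, **overrides) -> "SyntheticSpec":
        """Spec with lesion pixel dimensions scaled from the 512 px defaults."""
        f = size / 512
        base = LesionParams()
        lesions = overrides.pop(
            "lesions",
            LesionParams(
                spot_count=base.spot_count,
                spot_radius=(max(1.5, base.spot_radius[0] * f),
                             max(2.5, base.spot_radius[1] * f)),
                spot_intensity=base.spot_intensity,
                arc_amplitude=base.arc_amplitude,
                arc_thickness=max(2.0, base.arc_thickness * f),
                arc_intensity=base.arc_intensity,
            ),
        )
        return cls(size=size, lesions=lesions, **overrides)

    def to_json(self, path: str | Path) -> None:
        d = {**vars(self), "lesions": vars(self.lesions)}
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        d = json.loads(Path(path).read_text())
        d["lesions"] = LesionParams(**{k: tuple(v) if isinstance(v, list) else v
                                       for k, v in d["lesions"].items()})
        for k in ("ellipse_center", "ellipse_axes"):
            d[k] = tuple(d[k])
        return cls(**d)


def _ellipse_geometry(spec: SyntheticSpec):
    s = spec.size
    cx, cy = spec.ellipse_center[0] * s, spec.ellipse_center[1] * s
    ax, ay = spec.ellipse_axes[0] * s, spec.ellipse_axes[1] * s
    return cx, cy, ax, ay


def _render_spots(canvas: np.ndarray, spec: SyntheticSpec,
                  rng: np.random.Generator) -> None:
    cx, cy, ax, ay = _ellipse_geometry(spec)
    lp = spec.lesions
    s = spec.size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < lp.spot_count:
        attempts += 1
        if attempts > 500 * lp.spot_count:
            raise ValueError(
                f"cannot place {lp.spot_count} disjoint spots of radius "
                f"{lp.spot_radius} inside the fundus ellipse"
            )
        r = rng.uniform(*lp.spot_radius)
        # keep the whole blob support well inside the ellipse
        u, v = rng.uniform(-0.75, 0.75), rng.uniform(-0.75, 0.75)
        if u * u + v * v > 0.55:
            continue
        x, y = cx + u * ax, cy + v * ay
        # supports above half-intensity extend ~0.45 r from each center;
        # 1.5 (r + r') keeps a deep valley between neighboring blobs
        if any(np.hypot(x - px, y - py) < 1.5 * (r + pr) + 2 for px, py, pr in placed):
            continue
        placed.append((x, y, r))
        inten = rng.uniform(*lp.spot_intensity)
        sigma = r / 2.0
        blob = inten * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
        np.maximum(canvas, blob, out=canvas)


def _render_arc(canvas: np.ndarray, spec: SyntheticSpec,
                rng: np.random.Generator) -> None:
    cx, cy, ax, ay = _ellipse_geometry(spec)
    lp = spec.lesions
    s = spec.size
    # posterior (lower) arc of the ellipse, traced as a polyline
    half_span = lp.arc_amplitude * np.pi / 2
    phase = rng.uniform(-0.15, 0.15)
    t0 = np.pi / 2 - half_span + phase
    t1 = np.pi / 2 + half_span * lp.continuity + phase
    t = np.linspace(t0, t1, 400)
    px = cx + 0.72 * ax * np.cos(t)
    py = cy + 0.72 * ay * np.sin(t)   # y grows downward: pi/2 is the bottom
    # distance-to-polyline restricted to the arc's bounding box
    pad = 4 * lp.arc_thickness
    x0 = max(0, int(px.min() - pad)); x1 = min(s, int(px.max() + pad) + 1)
    y0 = max(0, int(py.min() - pad)); y1 = min(s, int(py.max() + pad) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
    dist = np.full(yy.shape, np.inf)
    for x, y in zip(px, py):
        np.minimum(dist, np.hypot(xx - x, yy - y), out=dist)
    profile = lp.arc_intensity * np.exp(-(dist**2) / (2 * (lp.arc_thickness / 1.5) ** 2))
    np.maximum(canvas[y0:y1, x0:x1], profile, out=canvas[y0:y1, x0:x1])


def generate_image(spec: SyntheticSpec, label: str, seed: int) -> RawImage:
    """Render one labeled synthetic B-scan; pure in (spec, label, seed)."""
    if label not in (CLASS_VO, CLASS_PVD):
        raise ValueError(f"unknown class {label!r}; expected {CLASS_VO} or {CLASS_PVD}")
    rng = np.random.default_rng(seed)
    s = spec.size
    cx, cy, ax, ay = _ellipse_geometry(spec)
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    inside = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    canvas = np.where(inside, spec.fundus_level, spec.background_level)
    if label == CLASS_VO:
        _render_spots(canvas, spec, rng)
    else:
        _render_arc(canvas, spec, rng)
    if spec.noise_level > 0:
        speckle = 1.0 + spec.noise_level * rng.uniform(-1.0, 1.0, size=(s, s))
        canvas = canvas * speckle
    return RawImage(np.clip(canvas, 0.0, 1.0)[:, :, None])


def _child_seed(base_seed: int, label: str, index: int) -> int:
    """Stable per-image seed below 2**31."""
    h = hashlib.sha256(f"{base_seed}:{label}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path) -> DatasetManifest:
    """Write ``n_per_class`` PNGs per class plus the CSV manifest.

    Returns the manifest; byte-identical across runs with the same spec.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for label in (CLASS_VO, CLASS_PVD):
        for i in range(spec.n_per_class):
            img = generate_image(spec, label, _child_seed(spec.seed, label, i))
            arr = (img.pixels[:, :, 0] * 255).round().astype(np.uint8)
            name = f"{label.lower()}_{i:04d}.png"
            Image.fromarray(arr, mode="L").save(out / name, format="PNG")
            rows.append({"path": name, "label": label})
    manifest = DatasetManifest(pd.DataFrame(rows))
    manifest.to_csv(out / "manifest.csv")
    spec.to_json(out / "synthetic_spec.json")
    return manifest
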