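"""Embedding gallery and exact k-nearest-neighbor classification.

The readout stage: every training image is embedded once into a labeled
*gallery*; a query embedding is classified by majority vote among its k
nearest gallery entries under Euclidean distance, with k = 2 as the default.

Tie handling is fully specified because k = 2 on a two-class problem ties
whenever the two neighbors disagree:

* distance ties inside the sort are broken by label (lexicographically),
  then insertion order — so the decision is invariant to permuting the
  gallery even when equidistant points carry different labels;
* vote ties fall back to the label of the single nearest neighbor — which
  makes even k behave like k = 1 exactly when the neighbors disagree.

Search is exact brute force; gallery sizes here never warrant indexing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .backbone import BranchNetwork
from .imaging import (
    DatasetManifest,
    PreprocessConfig,
    RawImage,
    load_image,
    preprocess_image,
)

__all__ = ["KnnConfig", "FeatureGallery", "build_gallery", "knn_classify",
           "predict_image", "predict_manifest"]


@dataclass(frozen=True)
class KnnConfig:
    k: int = 2
    # distance is Euclidean; vote ties fall back to the nearest neighbor

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class FeatureGallery:
    """Labeled embedding matrix with provenance."""

    vectors: np.ndarray          # (n, dim)
    labels: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or len(self.vectors) == 0:
            raise ValueError("gallery needs a nonempty (n, dim) matrix")
        if len(self.labels) != len(self.vectors):
            raise ValueError("labels must align with vectors")
        self.labels = list(self.labels)

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if not path.name.endswith(".npz"):
            path = Path(str(path) + ".npz")
        np.savez(path, vectors=self.vectors)
        meta = {"labels": self.labels, "dim": self.dim, **self.provenance}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "FeatureGallery":
        path = Path(path)
        if not path.name.endswith(".npz"):
            path = Path(str(path) + ".npz")
        meta = json.loads(Path(str(path) + ".json").read_text())
        with np.load(path) as data:
            vectors = data["vectors"]
        prov = {k: v for k, v in meta.items() if k not in ("labels", "dim")}
        return cls(vectors, meta["labels"], prov)


def build_gallery(
    net: BranchNetwork,
    images: np.ndarray,
    labels: list[str],
    provenance: dict | None = None,
) -> FeatureGallery:
    """Embed a preprocessed (N, C, H, W) stack into a labeled gallery."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 4 or len(images) == 0:
        raise ValueError("need a nonempty (N, C, H, W) image stack")
    if len(labels) != len(images):
        raise ValueError("labels must align with images")
    return FeatureGallery(net.embed_batch(images), list(labels), provenance or {})


def knn_classify(
    gallery: FeatureGallery, query: np.ndarray, config: KnnConfig | None = None
) -> tuple[str, list[tuple[int, float, str]]]:
    """Classify one query embedding.

    Returns the winning label and the audited neighbor list
    ``[(gallery_index, distance, label), ...]`` of length k, nearest first.
    """
    config = config or KnnConfig()
    if config.k > len(gallery):
        raise ValueError(f"k={config.k} exceeds gallery size {len(gallery)}")
    q = np.asarray(query, dtype=np.float64).reshape(-1)
    if q.shape[0] != gallery.dim:
        raise ValueError(f"query dim {q.shape[0]} != gallery dim {gallery.dim}")
    dists = np.linalg.norm(gallery.vectors - q, axis=1)
    label_rank = np.unique(gallery.labels, return_inverse=True)[1]
    order = np.lexsort((np.arange(len(dists)), label_rank, dists))[: config.k]
    neighbors = [(int(i), float(dists[i]), gallery.labels[i]) for i in order]
    votes: dict[str, int] = {}
    for _, _, lab in neighbors:
        votes[lab] = votes.get(lab, 0) + 1
    best = max(votes.values())
    winners = [lab for lab, v in votes.items() if v == best]
    label = neighbors[0][2] if len(winners) > 1 else winners[0]
    return label, neighbors


def predict_image(
    net: BranchNetwork,
    gallery: FeatureGallery,
    img: RawImage,
    preprocess: PreprocessConfig,
    config: KnnConfig | None = None,
) -> str:
    """Full inference path: preprocess -> embed -> KNN vote."""
    pre = preprocess_image(img, preprocess)
    vec = net.embed_batch(pre.pixels[None])[0]
    label, _ = knn_classify(gallery, vec, config)
    return label


def predict_manifest(
    net: BranchNetwork,
    gallery: FeatureGallery,
    manifest: DatasetManifest,
    preprocess: PreprocessConfig,
    config: KnnConfig | None = None,
    images_root: str | Path = ".",
) -> list[str]:
    """Predict every image in a manifest (paths resolved against a root)."""
    root = Path(images_root)
    out = []
    for path in manifest.records["path"]:
        img = load_image(root / path, to_rgb=preprocess.to_rgb)
        out.append(predict_image(net, gallery, img, preprocess, config))
    return out
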