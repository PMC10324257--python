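"""High-level modelling interface.

:class:`SiameseKNN` bundles the full pipeline — preprocessing, the shared
siamese branch, contrastive training, the embedding gallery and the KNN
readout — behind a model object constructed from a dataset manifest.
``fit()`` runs training and returns a :class:`SiameseKNNResults` carrying the
trained branch, the loss history, the gallery and (when a test split is
available) the evaluation metrics, with ``summary()``, ``predict()`` and
``save()`` hanging off it.

Example
-------
>>> model = SiameseKNN.from_manifest("data/manifest.csv", images_root="data",
...                                  **SiameseKNN.desk_profile())
>>> res = model.fit(seed=7)
>>> print(res.summary())
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .backbone import (
    BranchConfig,
    BranchNetwork,
    build_branch,
    load_checkpoint,
    save_checkpoint,
)
from .evaluation import (
    DEFAULT_POSITIVE_CLASS,
    MetricsReport,
    metrics_from_predictions,
)
from .imaging import (
    DatasetManifest,
    PreprocessConfig,
    RawImage,
    load_image,
    preprocess_image,
    stratified_split,
)
from .knn import FeatureGallery, KnnConfig, build_gallery, knn_classify
from .training import LossConfig, TrainConfig, train_model

__all__ = ["SiameseKNN", "SiameseKNNResults"]


def _load_stack(
    manifest: DatasetManifest, root: Path, pre: PreprocessConfig
) -> tuple[np.ndarray, list[str]]:
    images, labels = [], []
    for _, row in manifest.records.iterrows():
        img = load_image(root / row["path"], to_rgb=pre.to_rgb)
        images.append(preprocess_image(img, pre).pixels)
        labels.append(row["label"])
    return np.stack(images), labels


@dataclass
class SiameseKNN:
    """Two-class siamese metric-learning classifier with a KNN readout."""

    train_manifest: DatasetManifest
    test_manifest: DatasetManifest | None = None
    images_root: Path = Path(".")
    branch: BranchConfig = field(default_factory=BranchConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    knn: KnnConfig = field(default_factory=KnnConfig)
    positive_class: str = DEFAULT_POSITIVE_CLASS

    def __post_init__(self):
        self.images_root = Path(self.images_root)
        if len(self.train_manifest.classes) != 2:
            raise ValueError("training manifest must contain exactly two classes")

    # constructors -------------------------------------------------------
    @classmethod
    def from_manifest(
        cls,
        manifest: DatasetManifest | str | Path,
        images_root: str | Path = ".",
        train_fraction: float = 0.7,
        split_seed: int = 0,
        **configs,
    ) -> "SiameseKNN":
        """Build from an unsplit manifest (CSV/JSON path or object); applies
        the stratified train/test split."""
        if not isinstance(manifest, DatasetManifest):
            p = Path(manifest)
            manifest = (
                DatasetManifest.from_json(p)
                if p.suffix == ".json"
                else DatasetManifest.from_csv(p)
            )
        train_m, test_m = stratified_split(manifest, train_fraction, split_seed)
        return cls(train_m, test_m, Path(images_root), **configs)

    @classmethod
    def from_dataframe(
        cls, records: pd.DataFrame, images_root: str | Path = ".", **kwargs
    ) -> "SiameseKNN":
        return cls.from_manifest(DatasetManifest(records), images_root, **kwargs)

    @staticmethod
    def desk_profile(seed: int = 0) -> dict:
        """CPU-scale configuration: tiny branch, 64 px inputs, short training."""
        return {
            "branch": BranchConfig.tiny(),
            "preprocess": PreprocessConfig(crop=None, side=64),
            "train": TrainConfig(
                learning_rate=1e-3, batch_size=50, epochs=8, seed=seed
            ),
        }

    # fitting ------------------------------------------------------------
    def fit(self, seed: int | None = None) -> "SiameseKNNResults":
        """Train the branch, build the gallery, and evaluate the test split."""
        seed = self.train.seed if seed is None else seed
        tcfg = TrainConfig(
            learning_rate=self.train.learning_rate,
            batch_size=self.train.batch_size,
            epochs=self.train.epochs,
            pairs_per_epoch=self.train.pairs_per_epoch,
            positive_fraction=self.train.positive_fraction,
            seed=seed,
        )
        t0 = time.perf_counter()
        train_images, train_labels = _load_stack(
            self.train_manifest, self.images_root, self.preprocess
        )
        net = build_branch(self.branch, seed=seed)
        history = train_model(net, train_images, train_labels, tcfg, self.loss)
        gallery = build_gallery(
            net, train_images, train_labels, provenance={"seed": seed}
        )
        metrics = None
        predictions = None
        if self.test_manifest is not None and len(self.test_manifest) > 0:
            test_images, test_labels = _load_stack(
                self.test_manifest, self.images_root, self.preprocess
            )
            vecs = net.embed_batch(test_images)
            preds = [knn_classify(gallery, v, self.knn)[0] for v in vecs]
            metrics = metrics_from_predictions(
                test_labels, preds, self.positive_class
            )
            predictions = pd.DataFrame(
                {
                    "path": self.test_manifest.records["path"],
                    "label": test_labels,
                    "predicted": preds,
                }
            )
        return SiameseKNNResults(
            model=self,
            net=net,
            gallery=gallery,
            loss_history=history,
            metrics=metrics,
            predictions=predictions,
            seed=seed,
            fit_seconds=time.perf_counter() - t0,
        )


@dataclass
class SiameseKNNResults:
    """Fitted pipeline: trained branch, gallery, history, metrics."""

    model: SiameseKNN
    net: BranchNetwork
    gallery: FeatureGallery
    loss_history: list[float]
    metrics: MetricsReport | None
    predictions: pd.DataFrame | None
    seed: int
    fit_seconds: float = float("nan")

    @property
    def loss_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": range(len(self.loss_history)), "mean_loss": self.loss_history}
        )

    def predict(self, image: RawImage | str | Path) -> str:
        if not isinstance(image, RawImage):
            image = load_image(image, to_rgb=self.model.preprocess.to_rgb)
        pre = preprocess_image(image, self.model.preprocess)
        vec = self.net.embed_batch(pre.pixels[None])[0]
        return knn_classify(self.gallery, vec, self.model.knn)[0]

    def evaluate(self, manifest: DatasetManifest | None = None) -> MetricsReport:
        """Metrics on a manifest (default: the model's test split)."""
        if manifest is None:
            if self.metrics is not None:
                return self.metrics
            raise ValueError("no test split available; pass a manifest")
        images, labels = _load_stack(
            manifest, self.model.images_root, self.model.preprocess
        )
        vecs = self.net.embed_batch(images)
        preds = [knn_classify(self.gallery, v, self.model.knn)[0] for v in vecs]
        return metrics_from_predictions(labels, preds, self.model.positive_class)

    def summary(self) -> str:
        """Human-readable fit report."""
        lines = [
            "Siamese metric-learning classifier with KNN readout",
            "=" * 51,
            f"branch architecture : {self.model.branch.architecture}",
            f"attention           : {self.model.branch.attention.tag}",
            f"embedding dim       : {self.model.branch.embedding_dim}",
            f"training images     : {len(self.model.train_manifest)}",
            f"epochs run          : {len(self.loss_history)}",
            f"seed                : {self.seed}",
        ]
        if self.loss_history:
            lines += [
                f"first-epoch loss    : {self.loss_history[0]:.4f}",
                f"final-epoch loss    : {self.loss_history[-1]:.4f}",
            ]
        if self.metrics is not None:
            m = self.metrics
            lines += [
                "-" * 51,
                f"test images         : {m.counts.total}",
                f"positive class      : {m.positive_class}",
                f"accuracy            : {m.accuracy:.3f}",
                f"precision           : {m.precision:.3f}",
                f"recall              : {m.recall:.3f}",
                f"F1                  : {m.f1:.3f}",
            ]
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Write checkpoint, gallery, loss history and provenance."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_checkpoint(self.net, out / "checkpoint", extra={"epochs": len(self.loss_history)})
        self.gallery.save(out / "gallery")
        self.loss_frame.to_csv(out / "loss_history.csv", index=False)
        prov = {
            "seed": self.seed,
            "branch": self.model.branch.to_dict(),
            "n_train": len(self.model.train_manifest),
            "positive_class": self.model.positive_class,
        }
        if self.metrics is not None:
            prov["metrics"] = {
                k: v
                for k, v in self.metrics.as_row().items()
                if isinstance(v, (int, float, str, bool))
            }
        (out / "provenance.json").write_text(json.dumps(prov, indent=1))
        if self.predictions is not None:
            self.predictions.to_csv(out / "predictions.csv", index=False)

    @classmethod
    def load_network(cls, checkpoint_path: str | Path) -> BranchNetwork:
        return load_checkpoint(checkpoint_path)
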