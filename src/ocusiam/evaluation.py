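"""Classification metrics and the experiment harnesses.

Metrics follow the standard single-positive-class definitions

    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

with the division-by-zero convention "report 0 and set the degenerate flag"
so harness tables stay rectangular.  Because which class counts as positive
is an arbitrary choice on this two-class problem (PVD by default), a
macro-averaged variant over both class designations is reported alongside.

Three harnesses mirror the experiments a practitioner runs on this pipeline:
an attention ablation (none / channel / spatial / both), a sweep over the
KNN neighbor count k on a fixed gallery, and a comparison of classifier
heads (our KNN vs support-vector, random-forest and gradient-boosting heads
fitted on the same gallery embeddings).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .attention import AttentionConfig
from .backbone import BranchConfig, BranchNetwork, build_branch
from .knn import FeatureGallery, KnnConfig, build_gallery, knn_classify
from .training import LossConfig, TrainConfig, train_model

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ExperimentGrid",
    "confusion_from_predictions",
    "compute_metrics",
    "run_ablation",
    "run_k_sweep",
    "run_classifier_comparison",
    "DEFAULT_POSITIVE_CLASS",
]

DEFAULT_POSITIVE_CLASS = "PVD"

ATTENTION_VARIANTS = {
    "none": AttentionConfig(channel=False, spatial=False),
    "channel": AttentionConfig(channel=True, spatial=False),
    "spatial": AttentionConfig(channel=False, spatial=True),
    "both": AttentionConfig(channel=True, spatial=True),
}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    counts: ConfusionCounts
    positive_class: str = DEFAULT_POSITIVE_CLASS
    degenerate: bool = False
    macro_precision: float = float("nan")
    macro_recall: float = float("nan")
    macro_f1: float = float("nan")

    def as_row(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
            "positive_class": self.positive_class,
            "degenerate": self.degenerate,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }


def confusion_from_predictions(
    truth: Sequence[str], predicted: Sequence[str], positive_class: str
) -> ConfusionCounts:
    """Tally the 2x2 confusion table for the designated positive class."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predictions must align")
    classes = set(truth) | set(predicted)
    if len(classes) > 2:
        raise ValueError(f"expected two classes, saw {sorted(classes)}")
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} not among {sorted(classes)}")
    tp = sum(t == positive_class and p == positive_class for t, p in zip(truth, predicted))
    fn = sum(t == positive_class and p != positive_class for t, p in zip(truth, predicted))
    fp = sum(t != positive_class and p == positive_class for t, p in zip(truth, predicted))
    tn = sum(t != positive_class and p != positive_class for t, p in zip(truth, predicted))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _single_class_metrics(c: ConfusionCounts) -> tuple[float, float, float, bool]:
    degenerate = False
    if c.tp + c.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = c.tp / (c.tp + c.fn)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1, degenerate


def compute_metrics(
    counts: ConfusionCounts, positive_class: str = DEFAULT_POSITIVE_CLASS
) -> MetricsReport:
    """Accuracy / precision / recall / F1 from confusion counts."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated images")
    accuracy = (counts.tp + counts.tn) / counts.total
    precision, recall, f1, degenerate = _single_class_metrics(counts)
    # macro average: swap which class is positive and average the two views
    swapped = ConfusionCounts(tp=counts.tn, fp=counts.fn, tn=counts.tp, fn=counts.fp)
    p2, r2, f2, deg2 = _single_class_metrics(swapped)
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        counts=counts,
        positive_class=positive_class,
        degenerate=degenerate or deg2,
        macro_precision=(precision + p2) / 2,
        macro_recall=(recall + r2) / 2,
        macro_f1=(f1 + f2) / 2,
    )


def metrics_from_predictions(
    truth: Sequence[str],
    predicted: Sequence[str],
    positive_class: str = DEFAULT_POSITIVE_CLASS,
) -> MetricsReport:
    return compute_metrics(
        confusion_from_predictions(truth, predicted, positive_class), positive_class
    )


@dataclass(frozen=True)
class ExperimentGrid:
    """Named configurations shared by the harnesses."""

    attention_variants: tuple[str, ...] = ("none", "channel", "spatial", "both")
    ks: tuple[int, ...] = (2, 4, 8, 10)
    heads: tuple[str, ...] = ("knn", "svm", "random_forest", "gradient_boosting")
    seed: int = 0

    def __post_init__(self):
        if not self.attention_variants and not self.ks and not self.heads:
            raise ValueError("empty experiment grid")
        unknown = set(self.attention_variants) - set(ATTENTION_VARIANTS)
        if unknown:
            raise ValueError(f"unknown attention variants: {sorted(unknown)}")
        if len(set(self.attention_variants)) != len(self.attention_variants):
            raise ValueError("duplicate attention variants")


def _classify_matrix(
    gallery: FeatureGallery, vectors: np.ndarray, config: KnnConfig
) -> list[str]:
    return [knn_classify(gallery, v, config)[0] for v in vectors]


def run_ablation(
    grid: ExperimentGrid,
    base_config: BranchConfig,
    train_images: np.ndarray,
    train_labels: Sequence[str],
    test_images: np.ndarray,
    test_labels: Sequence[str],
    tcfg: TrainConfig | None = None,
    lcfg: LossConfig | None = None,
    kcfg: KnnConfig | None = None,
    positive_class: str = DEFAULT_POSITIVE_CLASS,
) -> pd.DataFrame:
    """Train and score one pipeline per attention variant with shared seeds.

    Returns one row per variant; a variant that raises is recorded with
    ``status='failed'`` rather than silently dropped.  Loss histories are
    attached in the ``loss_history`` column (list of per-epoch means).
    """
    if not grid.attention_variants:
        raise ValueError("ablation grid has no attention variants")
    tcfg = tcfg or TrainConfig()
    kcfg = kcfg or KnnConfig()
    rows = []
    for variant in grid.attention_variants:
        row: dict = {"variant": variant, "status": "ok"}
        try:
            cfg = BranchConfig(
                architecture=base_config.architecture,
                pretrained=base_config.pretrained,
                attention=ATTENTION_VARIANTS[variant],
                embedding_dim=base_config.embedding_dim,
                input_size=base_config.input_size,
                input_channels=base_config.input_channels,
            )
            net = build_branch(cfg, seed=grid.seed)
            history = train_model(net, train_images, train_labels, tcfg, lcfg)
            gallery = build_gallery(net, train_images, list(train_labels))
            preds = _classify_matrix(gallery, net.embed_batch(test_images), kcfg)
            report = metrics_from_predictions(test_labels, preds, positive_class)
            row.update(report.as_row())
            row["loss_history"] = history
            row["final_loss"] = history[-1] if history else float("nan")
        except Exception as exc:  # recorded, not dropped
            row["status"] = "failed"
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def run_k_sweep(
    gallery: FeatureGallery,
    test_vectors: np.ndarray,
    test_labels: Sequence[str],
    ks: Sequence[int],
    positive_class: str = DEFAULT_POSITIVE_CLASS,
) -> pd.DataFrame:
    """Score KNN at each k on one fixed gallery (no retraining)."""
    import warnings

    uniq = list(dict.fromkeys(int(k) for k in ks))
    if len(uniq) != len(list(ks)):
        warnings.warn("duplicate k values deduplicated", stacklevel=2)
    rows = []
    for k in uniq:
        if k < 1 or k > len(gallery):
            raise ValueError(f"invalid k={k} for gallery of size {len(gallery)}")
        preds = _classify_matrix(gallery, test_vectors, KnnConfig(k=k))
        report = metrics_from_predictions(test_labels, preds, positive_class)
        rows.append({"k": k, **report.as_row()})
    return pd.DataFrame(rows)


def run_classifier_comparison(
    gallery: FeatureGallery,
    test_vectors: np.ndarray,
    test_labels: Sequence[str],
    heads: Sequence[str] = ("knn", "svm", "random_forest", "gradient_boosting"),
    kcfg: KnnConfig | None = None,
    positive_class: str = DEFAULT_POSITIVE_CLASS,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit alternative classifier heads on the gallery embeddings and score
    them identically to the KNN head."""
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.svm import SVC

    factories = {
        "svm": lambda: SVC(random_state=seed),
        "random_forest": lambda: RandomForestClassifier(random_state=seed),
        "gradient_boosting": lambda: GradientBoostingClassifier(random_state=seed),
    }
    kcfg = kcfg or KnnConfig()
    # validate ids up front: an unknown head is a caller error, not a failed row
    resolved: list[tuple[str, object | None]] = []
    for head in heads:
        if isinstance(head, tuple):  # (name, estimator with fit/predict)
            resolved.append(head)
        elif head == "knn":
            resolved.append(("knn", None))
        elif head in factories:
            resolved.append((head, factories[head]()))
        else:
            raise ValueError(f"unknown classifier head {head!r}")
    rows = []
    for name, clf in resolved:
        row: dict = {"head": name, "status": "ok"}
        try:
            if clf is None:
                preds = _classify_matrix(gallery, test_vectors, kcfg)
            else:
                clf.fit(gallery.vectors, gallery.labels)
                preds = [str(p) for p in clf.predict(test_vectors)]
            report = metrics_from_predictions(test_labels, preds, positive_class)
            row.update(report.as_row())
        except Exception as exc:  # isolated: one failed head leaves the rest intact
            row["status"] = "failed"
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
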