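"""Evaluation metrics on hard label masks: per-class Jaccard index (IoU)
and F1 score, with per-image and dataset-level averaging.

For a class ``c``, with ``GT`` and ``PO`` the sets of pixels labelled ``c``
in the ground truth and the prediction, ``J = |GT & PO| / |GT | PO|`` and
``F1 = 2 |GT & PO| / (|GT| + |PO|)``; the identity ``F1 = 2J / (1 + J)``
holds exactly.  A class absent from both masks has no defined score and is
reported as NaN and excluded from averages (scoring it 1 would inflate
easy images).  Dataset-level values are means over test images, per class
and macro over classes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


from .data_io import ClassScheme

__all__ = ["jaccard_index", "f1_score", "evaluate_dataset", "MetricsReport",
           "confusion_counts"]


def _nanmean(a, axis=None):
    """nanmean that treats an all-NaN slice as NaN without warning."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(a, axis=axis)


def _check_pair(pred: np.ndarray, truth: np.ndarray):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def confusion_counts(pred: np.ndarray, truth: np.ndarray, class_id: int):
    """Return ``(intersection, n_truth, n_pred)`` pixel counts for a class."""
    pred, truth = _check_pair(pred, truth)
    p = pred == class_id
    t = truth == class_id
    return int((p & t).sum()), int(t.sum()), int(p.sum())


def jaccard_index(pred: np.ndarray, truth: np.ndarray, class_id: int) -> float:
    """Intersection over union for one class; NaN if absent from both."""
    inter, nt, npred = confusion_counts(pred, truth, class_id)
    union = nt + npred - inter
    if union == 0:
        return float("nan")
    return inter / union


def f1_score(pred: np.ndarray, truth: np.ndarray, class_id: int) -> float:
    """Dice overlap of the class pixel sets; NaN if absent from both."""
    inter, nt, npred = confusion_counts(pred, truth, class_id)
    if nt + npred == 0:
        return float("nan")
    return 2.0 * inter / (nt + npred)


@dataclass
class MetricsReport:
    """Per-image x per-class Jaccard/F1 table plus the derived means."""

    scheme: ClassScheme
    jaccard: np.ndarray  # (n_images, n_classes), NaN where undefined
    f1: np.ndarray

    @property
    def per_class_jaccard(self) -> np.ndarray:
        """Dataset mean per class (images lacking the class excluded)."""
        return _nanmean(self.jaccard, axis=0)

    @property
    def per_class_f1(self) -> np.ndarray:
        return _nanmean(self.f1, axis=0)

    @property
    def per_image_jaccard(self) -> np.ndarray:
        return _nanmean(self.jaccard, axis=1)

    @property
    def per_image_f1(self) -> np.ndarray:
        return _nanmean(self.f1, axis=1)

    @property
    def mean_jaccard(self) -> float:
        """Macro mean: average over images, then over classes."""
        return float(_nanmean(self.per_class_jaccard))

    @property
    def mean_f1(self) -> float:
        return float(_nanmean(self.per_class_f1))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.jaccard.shape[0]):
            for c, name in enumerate(self.scheme.names):
                rows.append({"image": i, "class": name,
                             "jaccard": self.jaccard[i, c],
                             "f1": self.f1[i, c]})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        summary = pd.DataFrame(
            [{"image": "dataset_mean", "class": name,
              "jaccard": self.per_class_jaccard[c],
              "f1": self.per_class_f1[c]}
             for c, name in enumerate(self.scheme.names)]
            + [{"image": "dataset_mean", "class": "__macro__",
                "jaccard": self.mean_jaccard, "f1": self.mean_f1}])
        pd.concat([frame, summary]).to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> dict:
        def clean(x):
            return None if np.isnan(x) else float(x)

        doc = {
            "classes": list(self.scheme.names),
            "per_class": {name: {"jaccard": clean(self.per_class_jaccard[c]),
                                 "f1": clean(self.per_class_f1[c])}
                          for c, name in enumerate(self.scheme.names)},
            "mean_jaccard": self.mean_jaccard,
            "mean_f1": self.mean_f1,
            "n_images": int(self.jaccard.shape[0]),
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=2))
        return doc


def evaluate_dataset(preds: list[np.ndarray], truths: list[np.ndarray],
                     scheme: ClassScheme) -> MetricsReport:
    """Score aligned lists of predicted and ground-truth masks."""
    if len(preds) != len(truths):
        raise ValueError("preds and truths must have equal length")
    if not preds:
        raise ValueError("no images to evaluate")
    n, c = len(preds), scheme.n_classes
    jac = np.full((n, c), np.nan)
    f1 = np.full((n, c), np.nan)
    for i, (p, t) in enumerate(zip(preds, truths)):
        for cid in range(c):
            jac[i, cid] = jaccard_index(p, t, cid)
            f1[i, cid] = f1_score(p, t, cid)
    return MetricsReport(scheme, jac, f1)
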