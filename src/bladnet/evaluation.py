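"""One-vs-rest diagnostic metrics, ROC/AUC, and report generation.

Each class is treated in turn as the positive class and all remaining classes
as negative; a study counts as predicted-positive when its positive-class
probability reaches the decision threshold (default 0.5). Rates are kept at
full precision internally and rounded to two decimals only at serialisation.
A metric whose denominator is zero is reported as NA, never as 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "ROCCurve",
    "MetricsReport",
    "confusion_counts",
    "sensitivity",
    "specificity",
    "precision",
    "f1",
    "roc_auc",
    "build_report",
]


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str = ""

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _positive_scores(pred, positive_class, class_codes):
    pred = np.asarray(pred)
    if pred.ndim == 2:
        if class_codes is None:
            raise ValidationError("class_codes is required with a 2-D probability matrix")
        return pred[:, list(class_codes).index(positive_class)].astype(float)
    return pred


def confusion_counts(
    y_true,
    pred,
    positive_class,
    threshold: float = 0.5,
    class_codes: list | None = None,
) -> ConfusionCounts:
    """Tally one-vs-rest counts from hard labels or probability scores.

    ``pred`` may be hard labels (same dtype as ``y_true``), a 1-D array of
    positive-class probabilities, or an n x c probability matrix together with
    ``class_codes``. With probabilities, predicted-positive means probability
    >= ``threshold``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    y_true = np.asarray(y_true)
    pred = np.asarray(pred)
    if len(y_true) != len(pred):
        raise ValidationError(f"length mismatch: {len(y_true)} truths, {len(pred)} predictions")
    actual_pos = y_true == positive_class
    if pred.ndim == 2 or np.issubdtype(pred.dtype, np.floating):
        pred_pos = _positive_scores(pred, positive_class, class_codes) >= threshold
    else:
        pred_pos = pred == positive_class
    tp = int(np.sum(actual_pos & pred_pos))
    fp = int(np.sum(~actual_pos & pred_pos))
    fn = int(np.sum(actual_pos & ~pred_pos))
    tn = int(np.sum(~actual_pos & ~pred_pos))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, positive_class=str(positive_class))


def _rate(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def sensitivity(c: ConfusionCounts) -> float | None:
    """tp / (tp + fn), in percent; NA (None) when no positives exist."""
    return _rate(c.tp, c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float | None:
    """tn / (tn + fp), in percent."""
    return _rate(c.tn, c.tn + c.fp)


def precision(c: ConfusionCounts) -> float | None:
    """tp / (tp + fp), in percent."""
    return _rate(c.tp, c.tp + c.fp)


def f1(c: ConfusionCounts) -> float | None:
    """2 tp / (2 tp + fp + fn), in percent; equals the harmonic mean of
    precision and sensitivity wherever both are defined."""
    return _rate(2 * c.tp, 2 * c.tp + c.fp + c.fn)


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(y_true, scores, positive_class) -> tuple[ROCCurve, float]:
    """ROC curve over grouped unique score thresholds and trapezoidal AUC.

    Tied scores are grouped into a single threshold step, which makes the
    trapezoidal AUC equal the Mann-Whitney pairwise-ranking probability with
    half credit for ties.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"ROC needs both classes present; positives={n_pos}, negatives={n_neg}"
        )
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    pos_sorted = pos[order]
    # group indices of the last element of each tie block
    is_last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    cum_tp = np.cumsum(pos_sorted)[is_last]
    cum_fp = np.cumsum(~pos_sorted)[is_last]
    tpr = np.r_[0.0, cum_tp / n_pos]
    fpr = np.r_[0.0, cum_fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[is_last]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds), auc


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics (percent; AUC as a fraction) + accuracy."""

    classes: list[str]
    per_class: dict[str, dict[str, float | int | None]]
    threshold: float
    accuracy: float | None = None
    roc_curves: dict[str, ROCCurve] = field(default_factory=dict)

    @staticmethod
    def _round(x):
        return None if x is None else round(x, 2)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in self.classes:
            m = self.per_class[cls]
            rows.append(
                {
                    "class": cls,
                    "sensitivity": self._round(m["sensitivity"]),
                    "specificity": self._round(m["specificity"]),
                    "precision": self._round(m["precision"]),
                    "f1": self._round(m["f1"]),
                    "auc": None if m["auc"] is None else round(m["auc"], 4),
                    "n": m["n"],
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False, na_rep="NA")
        return path

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "threshold": self.threshold,
            "accuracy": self._round(self.accuracy),
            "per_class": {
                cls: {
                    k: (self._round(v) if k != "auc" else (None if v is None else round(v, 4)))
                    for k, v in m.items()
                }
                for cls, m in self.per_class.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            path = Path(path)
            path.parent.mkdir(parents=True, exist_ok=True)
            path.write_text(text)
        return text

    def write_roc_csv(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for cls, curve in self.roc_curves.items():
            p = out_dir / f"roc_{cls}.csv"
            pd.DataFrame(
                {"threshold": curve.thresholds, "fpr": curve.fpr, "tpr": curve.tpr}
            ).to_csv(p, index=False)
            paths.append(p)
        return paths


def build_report(y_true, probs, class_codes, threshold: float = 0.5) -> MetricsReport:
    """One-vs-rest loop over classes; AUC is NA for a class absent from truth."""
    y_true = np.asarray(y_true)
    probs = np.asarray(probs, dtype=float)
    class_codes = list(class_codes)
    per_class: dict[str, dict] = {}
    curves: dict[str, ROCCurve] = {}
    for cls in class_codes:
        c = confusion_counts(y_true, probs, cls, threshold=threshold, class_codes=class_codes)
        scores = _positive_scores(probs, cls, class_codes)
        pos = int((y_true == cls).sum())
        if 0 < pos < len(y_true):
            curve, auc = roc_auc(y_true, scores, cls)
            curves[cls] = curve
        else:
            auc = None
        per_class[cls] = {
            "sensitivity": sensitivity(c),
            "specificity": specificity(c),
            "precision": precision(c),
            "f1": f1(c),
            "auc": auc,
            "n": pos,
            "tp": c.tp,
            "fp": c.fp,
            "tn": c.tn,
            "fn": c.fn,
        }
    pred_labels = np.asarray(class_codes, dtype=object)[np.argmax(probs, axis=1)]
    accuracy = float(np.mean(pred_labels == y_true.astype(object))) if len(y_true) else None
    return MetricsReport(
        classes=class_codes,
        per_class=per_class,
        threshold=threshold,
        accuracy=accuracy,
        roc_curves=curves,
    )
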