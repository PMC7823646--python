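"""One-vs-rest evaluation metrics and group comparison.

Multiclass pixel classification is evaluated per class under the
one-vs-rest strategy (one class positive, all others negative), giving
per-class TP/FP/FN/TN and hence precision, recall and F1.  Overall
quality is summarised by accuracy and the Hamming loss: the per-sample
fraction of mismatching one-hot indicators, averaged over samples.  For
single-label one-hot data every misclassification flips exactly two
indicators, so Hamming loss = 2 (1 - accuracy) / N with N classes — the
identity that ties the two overall metrics together.  Kruskal-Wallis
rank tests compare pooled one-vs-rest metrics between methods or camera
positions without distributional assumptions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    EncodingError,
    InvalidComparisonError,
    InvalidParameterError,
    ShapeError,
)


def _round_half_up(value: float, decimals: int) -> float:
    """Decimal rounding, halves away from zero (print convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _check_pair(y_true, y_pred):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ShapeError("label sequences must have equal length")
    return y_true, y_pred


def one_vs_rest_counts(y_true, y_pred, target_class) -> ConfusionCounts:
    """TP/FP/FN/TN treating ``target_class`` as positive."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    pos_t = y_true == target_class
    pos_p = y_pred == target_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); 0 when the denominator is 0."""
    d = c.tp + c.fp
    return c.tp / d if d else 0.0


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); 0 when the denominator is 0."""
    d = c.tp + c.fn
    return c.tp / d if d else 0.0


def f1_score(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 on a 0 + 0 pair."""
    p, r = precision(c), recall(c)
    return 2.0 * p * r / (p + r) if (p + r) else 0.0


def f1_from_precision_recall(p: float, r: float) -> float:
    """Harmonic mean of already-computed precision and recall values."""
    return 2.0 * p * r / (p + r) if (p + r) else 0.0


def accuracy(y_true, y_pred) -> float:
    """Fraction of exact label matches."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    if len(y_true) == 0:
        raise InvalidParameterError("cannot score empty sequences")
    return float(np.mean(y_true == y_pred))


def hamming_loss(y_true_onehot, y_pred_onehot) -> float:
    """Mean over samples of the per-sample indicator mismatch fraction.

    Rows must be valid one-hot vectors.  For single-label data this
    equals 2 (1 - accuracy) / n_classes.
    """
    Yt = np.asarray(y_true_onehot)
    Yp = np.asarray(y_pred_onehot)
    if Yt.shape != Yp.shape or Yt.ndim != 2:
        raise ShapeError("one-hot matrices must share a 2-D shape")
    for Y in (Yt, Yp):
        if not (np.isin(Y, (0, 1)).all() and (Y.sum(axis=1) == 1).all()):
            raise EncodingError("rows must be one-hot indicator vectors")
    return float(np.mean(Yt != Yp))


def hamming_from_accuracy(acc: float, n_classes: int) -> float:
    """The single-label identity: Hamming loss = 2 (1 - acc) / N."""
    return 2.0 * (1.0 - acc) / n_classes


@dataclass
class KruskalResult:
    """Kruskal-Wallis H, degrees of freedom, p value and group sizes."""

    h_statistic: float
    df: int
    p_value: float
    group_sizes: tuple[int, ...]


def kruskal_wallis(groups) -> KruskalResult:
    """Rank-based H test with tie correction, chi-square approximation.

    All-tied data (zero rank variance) returns H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise InvalidParameterError("need >= 2 non-empty groups")
    sizes = tuple(len(g) for g in groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return KruskalResult(0.0, len(groups) - 1, 1.0, sizes)
    h, p = stats.kruskal(*groups)
    return KruskalResult(float(h), len(groups) - 1, float(p), sizes)


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics plus the overall metrics.

    ``per_class`` maps class name -> dict with keys counts, precision,
    recall, f1.  Print convention: 2 decimals for per-class metrics,
    3 decimals for accuracy and Hamming loss, halves away from zero.
    """

    per_class: dict[str, dict]
    accuracy: float
    hamming_loss: float
    n_samples: int
    method: str = ""
    camera_position: str = ""

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(self.per_class)

    @property
    def n_classes(self) -> int:
        return len(self.per_class)

    @classmethod
    def from_predictions(
        cls, y_true, y_pred, class_names, method="", camera_position=""
    ) -> "MetricsReport":
        y_true, y_pred = _check_pair(y_true, y_pred)
        per_class = {}
        for i, name in enumerate(class_names):
            c = one_vs_rest_counts(y_true, y_pred, i)
            per_class[name] = {
                "counts": c,
                "precision": precision(c),
                "recall": recall(c),
                "f1": f1_score(c),
            }
        acc = accuracy(y_true, y_pred)
        n = len(class_names)
        eye = np.eye(n, dtype=int)
        ham = hamming_loss(eye[y_true], eye[y_pred])
        return cls(per_class, acc, ham, len(y_true), method, camera_position)

    def summary_frame(self) -> pd.DataFrame:
        """Per-class metric table, printed to the 2-decimal convention."""
        rows = {
            metric: [
                _round_half_up(self.per_class[c][metric], 2)
                for c in self.per_class
            ]
            for metric in ("precision", "recall", "f1")
        }
        return pd.DataFrame(rows, index=list(self.per_class)).T

    def summary(self) -> str:
        head = (
            f"method={self.method or '-'} position={self.camera_position or '-'} "
            f"n={self.n_samples}\n"
            f"accuracy={_round_half_up(self.accuracy, 3):.3f} "
            f"Ha.loss={_round_half_up(self.hamming_loss, 3):.3f}\n"
        )
        return head + self.summary_frame().to_string(float_format="%.2f")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "camera_position": self.camera_position,
            "n_samples": self.n_samples,
            "accuracy": self.accuracy,
            "hamming_loss": self.hamming_loss,
            "per_class": {
                name: {
                    "tp": m["counts"].tp,
                    "fp": m["counts"].fp,
                    "fn": m["counts"].fn,
                    "tn": m["counts"].tn,
                    "precision": m["precision"],
                    "recall": m["recall"],
                    "f1": m["f1"],
                }
                for name, m in self.per_class.items()
            },
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "MetricsReport":
        d = json.loads(Path(path).read_text())
        per_class = {
            name: {
                "counts": ConfusionCounts(m["tp"], m["fp"], m["fn"], m["tn"]),
                "precision": m["precision"],
                "recall": m["recall"],
                "f1": m["f1"],
            }
            for name, m in d["per_class"].items()
        }
        return cls(
            per_class,
            d["accuracy"],
            d["hamming_loss"],
            d["n_samples"],
            d["method"],
            d["camera_position"],
        )


def comparison_table(reports: list[MetricsReport]) -> pd.DataFrame:
    """Stack reports into a tidy frame (rows: metric x position x method)."""
    rows = []
    for rep in reports:
        rows.append(
            {
                "metric": "accuracy",
                "position": rep.camera_position,
                "method": rep.method,
                "value": _round_half_up(rep.accuracy, 3),
            }
        )
        rows.append(
            {
                "metric": "hamming_loss",
                "position": rep.camera_position,
                "method": rep.method,
                "value": _round_half_up(rep.hamming_loss, 3),
            }
        )
        for name, m in rep.per_class.items():
            for metric in ("precision", "recall", "f1"):
                rows.append(
                    {
                        "metric": metric,
                        "position": rep.camera_position,
                        "method": rep.method,
                        "class": name,
                        "value": _round_half_up(m[metric], 2),
                    }
                )
    return pd.DataFrame(rows)


def compare_methods(
    report_a: MetricsReport, report_b: MetricsReport
) -> dict[str, KruskalResult]:
    """Kruskal-Wallis on pooled per-class metrics grouped by report.

    Typically the two reports are the kNN and network results on the same
    hold-out; the test asks whether the one-vs-rest metric distributions
    differ between the methods.
    """
    if report_a.class_names != report_b.class_names:
        raise InvalidComparisonError("reports cover different class sets")
    out = {}
    for metric in ("precision", "recall", "f1"):
        g_a = [report_a.per_class[c][metric] for c in report_a.class_names]
        g_b = [report_b.per_class[c][metric] for c in report_b.class_names]
        out[metric] = kruskal_wallis([g_a, g_b])
    return out


def compare_groups(groups: dict[str, list[float]]) -> KruskalResult:
    """Kruskal-Wallis across named groups (e.g. one per camera position)."""
    return kruskal_wallis(list(groups.values()))
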