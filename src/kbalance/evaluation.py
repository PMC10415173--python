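"""Macro-average precision (MAP) and per-class error tallies.

MAP is the unweighted mean over classes of the one-vs-rest precision
TP_i / (TP_i + FP_i), so every class counts equally regardless of how
many test sequences it has. The class set is the union of true and
predicted labels, ordered lexicographically; a class that is never
predicted (TP + FP = 0) scores precision 0 and is counted in
``n_undefined`` so the alternative convention can be recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ConfusionTally", "EvaluationReport", "tally", "macro_average_precision", "map_score"]


@dataclass
class ConfusionTally:
    """One-vs-rest counts per class (sorted class order)."""

    classes: list[str]
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    support: np.ndarray


@dataclass
class EvaluationReport:
    map: float
    per_class_precision: dict[str, float] = field(default_factory=dict)
    n_undefined: int = 0

    def to_dict(self) -> dict:
        return {"map": self.map,
                "per_class_precision": self.per_class_precision,
                "n_undefined": self.n_undefined}


def tally(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> ConfusionTally:
    """Count TP/FP/FN per class over the union of observed label sets."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"label vectors differ in length: {len(true_labels)} vs {len(predicted_labels)}")
    if len(true_labels) == 0:
        raise ValueError("cannot tally empty label vectors")
    classes = sorted(set(true_labels) | set(predicted_labels))
    idx = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    tp = np.zeros(k, dtype=np.int64)
    fp = np.zeros(k, dtype=np.int64)
    fn = np.zeros(k, dtype=np.int64)
    support = np.zeros(k, dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        ti, pi = idx[t], idx[p]
        support[ti] += 1
        if ti == pi:
            tp[ti] += 1
        else:
            fp[pi] += 1
            fn[ti] += 1
    return ConfusionTally(classes=classes, tp=tp, fp=fp, fn=fn, support=support)


def macro_average_precision(t: ConfusionTally) -> EvaluationReport:
    """MAP = mean_i TP_i / (TP_i + FP_i), zero-denominator classes score 0."""
    denom = t.tp + t.fp
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(denom > 0, t.tp / np.maximum(denom, 1), 0.0)
    n_undefined = int((denom == 0).sum())
    return EvaluationReport(
        map=float(prec.mean()),
        per_class_precision={c: float(p) for c, p in zip(t.classes, prec)},
        n_undefined=n_undefined,
    )


def map_score(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> float:
    """Convenience: MAP straight from label vectors."""
    return macro_average_precision(tally(true_labels, predicted_labels)).map
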