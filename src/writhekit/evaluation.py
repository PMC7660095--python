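"""Frame-level detection metrics and recording-level WM/PR classification.

Two evaluation planes, with deliberately different positive classes:

* frame level — the detected event, writhing movement (WM), is positive:
  accuracy, sensitivity, specificity and F1 over pooled frame-wise
  confusions between predicted timelines and the reference labels;
* recording level — poor repertoire (PR) is positive, the screening target:
  a recording is called PR when its detected WM percentage falls *below* a
  threshold; sweeping the threshold over all observed percentages yields a
  ROC curve whose AUC (trapezoidal rule) summarizes WM/PR separability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    """Frame or recording confusion counts, positive class fixed by caller."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_arrays(cls, pred: np.ndarray, truth: np.ndarray) -> "ConfusionCounts":
        pred = np.asarray(pred, bool)
        truth = np.asarray(truth, bool)
        if pred.shape != truth.shape:
            raise ValueError("prediction and truth lengths differ")
        return cls(
            tp=int(np.sum(pred & truth)),
            fp=int(np.sum(pred & ~truth)),
            fn=int(np.sum(~pred & truth)),
            tn=int(np.sum(~pred & ~truth)),
        )


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """ACC, SENS, SPEC, F1 in percent; NaN (undefined) on zero denominators."""
    if c.total == 0:
        raise ValueError("empty confusion table")

    def ratio(num: int, den: int) -> float:
        return 100.0 * num / den if den else float("nan")

    return {
        "ACC": ratio(c.tp + c.tn, c.total),
        "SENS": ratio(c.tp, c.tp + c.fn),
        "SPEC": ratio(c.tn, c.tn + c.fp),
        "F1": ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


def detection_metrics(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Frame-wise metrics with WM positive, both inputs boolean frame masks."""
    return metrics_from_counts(ConfusionCounts.from_arrays(pred, truth))


def wm_percentage(frame_pred: np.ndarray) -> float:
    """Percentage of frames predicted WM in a timeline."""
    frame_pred = np.asarray(frame_pred, bool)
    if frame_pred.size == 0:
        raise ValueError("empty timeline")
    return 100.0 * float(frame_pred.mean())


@dataclass(frozen=True)
class RocCurve:
    """Threshold sweep of the recording-level WM/PR rule (PR positive).

    ``fpr``/``tpr`` are aligned with ``thresholds`` (ascending); as the
    threshold rises, more recordings are called PR, so both rates are
    non-decreasing. The curve is closed at (0,0) and (1,1) by the -inf/+inf
    sentinel thresholds. AUC by the trapezoidal rule.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def recording_roc(
    percentages: Mapping[str, float], groups: Mapping[str, str]
) -> RocCurve:
    """ROC over the rule "call PR when WM% < threshold".

    ``percentages`` maps recording_id → detected WM percentage; ``groups``
    maps recording_id → "WM" or "PR" (the expert division). PR is the
    positive (screening) class. Ties at a threshold resolve by the strict
    inequality. Raises on one-class input.
    """
    recs = sorted(percentages)
    unknown = [r for r in recs if groups.get(r) not in ("WM", "PR")]
    if unknown:
        raise ValueError(f"recordings without a WM/PR group: {unknown}")
    pct = np.array([percentages[r] for r in recs])
    is_pr = np.array([groups[r] == "PR" for r in recs])
    n_pr = int(is_pr.sum())
    n_wm = len(recs) - n_pr
    if n_pr == 0 or n_wm == 0:
        raise ValueError("ROC needs at least one WM and one PR recording")
    thresholds = np.concatenate([[-np.inf], np.unique(pct), [np.inf]])
    tpr = np.empty_like(thresholds)
    fpr = np.empty_like(thresholds)
    for i, thr in enumerate(thresholds):
        called_pr = pct < thr
        tpr[i] = np.sum(called_pr & is_pr) / n_pr
        fpr[i] = np.sum(called_pr & ~is_pr) / n_wm
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds, fpr, tpr, auc)
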