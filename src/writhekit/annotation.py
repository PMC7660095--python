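"""Consensus ground truth from multiple experts and inter-rater agreement.

Experts independently mark the intervals where the infant shows writhing
movement; they agree on the phenomenon but not on exact boundaries. Ground
truth is therefore built as the set of frames marked by at least N of the K
experts — fragments shrink monotonically as N grows, trading recall of the
training label for confidence. Frame-level agreement between expert pairs
(accuracy and F1, pooled over recordings) quantifies how consistent the
human reference itself is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import WindowSpec
from .pose_io import ExpertIntervals


@dataclass(frozen=True)
class ConsensusLabels:
    """Per-frame WM/not-WM labels at consensus level N."""

    recording_id: str
    n_required: int
    fps: float
    frame_labels: np.ndarray  # bool, shape (n_frames,)


@dataclass(frozen=True)
class WindowLabel:
    """WM/OM label of one analysis window with its WM frame fraction."""

    window_start_s: float
    label: str  # "WM" | "OM"
    wm_fraction: float


def intervals_to_frames(
    intervals: Sequence[tuple[float, float]], fps: float, n_frames: int
) -> np.ndarray:
    """Boolean frame mask: frame f is inside iff start <= f/fps < end."""
    t = np.arange(n_frames) / fps
    mask = np.zeros(n_frames, dtype=bool)
    for s, e in intervals:
        mask |= (t >= s) & (t < e)
    return mask


def consensus(
    experts: Sequence[ExpertIntervals], N: int, fps: float, duration_s: float
) -> ConsensusLabels:
    """Frames marked WM by at least N of the given experts."""
    if not (1 <= N <= len(experts)):
        raise ValueError(f"N must be in [1, {len(experts)}], got {N}")
    rec_ids = {e.recording_id for e in experts}
    if len(rec_ids) != 1:
        raise ValueError(f"experts span multiple recordings: {sorted(rec_ids)}")
    n_frames = int(round(duration_s * fps))
    counts = np.zeros(n_frames, dtype=int)
    for e in experts:
        counts += intervals_to_frames(e.intervals, fps, n_frames)
    return ConsensusLabels(experts[0].recording_id, N, fps, counts >= N)


def label_windows(
    labels: ConsensusLabels, spec: WindowSpec, threshold: float = 0.5
) -> list[WindowLabel]:
    """Label each window WM iff its WM frame fraction reaches ``threshold``.

    Uses the same frame-index window grid as the feature extractor, so
    features and labels align window for window.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    out = []
    for i0, i1 in spec.frame_windows(len(labels.frame_labels), labels.fps):
        frac = float(labels.frame_labels[i0:i1].mean())
        out.append(
            WindowLabel(i0 / labels.fps, "WM" if frac >= threshold else "OM", frac)
        )
    return out


def labels_to_intervals(frame_labels: np.ndarray, fps: float) -> list[tuple[float, float]]:
    """Contiguous True runs of a frame mask as half-open [start_s, end_s) intervals."""
    padded = np.concatenate([[False], np.asarray(frame_labels, bool), [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return [(s / fps, e / fps) for s, e in zip(edges[::2], edges[1::2])]


# ---------------------------------------------------------------------------
# Inter-expert agreement
# ---------------------------------------------------------------------------

def pairwise_agreement(
    a: Mapping[str, np.ndarray], b: Mapping[str, np.ndarray]
) -> tuple[float, float]:
    """Frame-level (accuracy %, F1 %) between two raters' frame labels.

    ``a`` and ``b`` map recording_id → boolean WM frame mask. Frames of all
    shared recordings are pooled into one contingency table; accuracy =
    (TP+TN)/total and F1 = 2TP/(2TP+FP+FN) with WM positive, both ×100.
    """
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("raters share no recordings")
    la = np.concatenate([np.asarray(a[r], bool) for r in shared])
    lb = np.concatenate([np.asarray(b[r], bool) for r in shared])
    if la.shape != lb.shape:
        raise ValueError("frame label lengths differ on shared recordings")
    tp = int(np.sum(la & lb))
    fp = int(np.sum(~la & lb))
    fn = int(np.sum(la & ~lb))
    tn = int(np.sum(~la & ~lb))
    acc = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    f1 = 100.0 * 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
    return acc, f1


def agreement_matrix(
    frame_labels: Mapping[str, Mapping[str, np.ndarray]]
) -> pd.DataFrame:
    """K×K rater-agreement table: accuracy above the diagonal, F1 below.

    ``frame_labels`` maps expert_id → (recording_id → frame mask). The layout
    mirrors the conventional pairwise-agreement table: entry (i, j) with
    i < j holds accuracy, i > j holds F1; the diagonal is NaN.
    """
    experts = sorted(frame_labels)
    mat = pd.DataFrame(np.nan, index=experts, columns=experts)
    for i, ei in enumerate(experts):
        for j, ej in enumerate(experts):
            if i == j:
                continue
            acc, f1 = pairwise_agreement(frame_labels[ei], frame_labels[ej])
            mat.loc[ei, ej] = acc if i < j else f1
    return mat


def mean_agreement(
    frame_labels: Mapping[str, Mapping[str, np.ndarray]]
) -> tuple[float, float]:
    """Mean pairwise (accuracy %, F1 %) over all unordered expert pairs."""
    experts = sorted(frame_labels)
    accs, f1s = [], []
    for i, ei in enumerate(experts):
        for ej in experts[i + 1 :]:  # noqa: E203
            acc, f1 = pairwise_agreement(frame_labels[ei], frame_labels[ej])
            accs.append(acc)
            f1s.append(f1)
    return float(np.mean(accs)), float(np.mean(f1s))


def expert_frame_labels(
    annotations: Sequence[ExpertIntervals],
    durations: Mapping[str, float],
    fps: Mapping[str, float] | float,
) -> dict[str, dict[str, np.ndarray]]:
    """Rasterize annotations: expert_id → (recording_id → frame mask).

    Every listed expert gets a mask for every recording in ``durations``;
    recordings an expert left unmarked get an all-False mask (the expert saw
    no writhing movement there), so pairwise pooling covers the same frames
    for every pair.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for ann in annotations:
        rec = ann.recording_id
        if rec not in durations:
            continue
        f = fps[rec] if isinstance(fps, Mapping) else fps
        n = int(round(durations[rec] * f))
        out.setdefault(ann.expert_id, {})[rec] = intervals_to_frames(
            ann.intervals, f, n
        )
    for expert, per_rec in out.items():
        for rec, dur in durations.items():
            if rec not in per_rec:
                f = fps[rec] if isinstance(fps, Mapping) else fps
                per_rec[rec] = np.zeros(int(round(dur * f)), dtype=bool)
    return out
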