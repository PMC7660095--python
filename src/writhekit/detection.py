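"""Window classification, recording-level LOOCV, and overlap voting.

Each analysis window's 16-feature vector is classified WM or OM by one of
three detectors behind a uniform interface: an RBF-kernel SVM, a random
forest, or linear discriminant analysis. Evaluation is leave-one-recording-
out: the detector (and, for SVM/LDA, the per-feature z-score standardization)
is fitted on all windows of the other recordings and applied to the held-out
one, so no test-fold statistic ever enters training. Overlapping window
predictions are reduced to a per-frame timeline by majority vote, with exact
ties and uncovered frames resolved to OM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import evaluation
from .annotation import ConsensusLabels, WindowLabel
from .features import FEATURE_COLUMNS, FrameFeatures, WindowSpec

DETECTOR_KINDS = ("svm_rbf", "random_forest", "lda")

#: CLI-friendly aliases for detector kinds.
MODEL_ALIASES = {"svm": "svm_rbf", "rf": "random_forest", "da": "lda"}


@dataclass(frozen=True)
class DetectorSpec:
    """Choice of window classifier plus hyperparameters and seed."""

    kind: str = "svm_rbf"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 42

    def __post_init__(self) -> None:
        kind = MODEL_ALIASES.get(self.kind, self.kind)
        object.__setattr__(self, "kind", kind)
        if kind not in DETECTOR_KINDS:
            raise ValueError(f"kind must be one of {DETECTOR_KINDS}, got {kind!r}")


def make_detector(spec: DetectorSpec):
    """Build the sklearn estimator for a spec.

    SVM and LDA are wrapped with per-feature z-score standardization (an
    RBF kernel on heterogeneous feature scales is degenerate); the random
    forest is scale-equivariant and receives raw features. Fitting inside a
    Pipeline guarantees the scaler sees training folds only.
    """
    hp = dict(spec.hyperparameters)
    if spec.kind == "svm_rbf":
        hp.setdefault("C", 1.0)
        hp.setdefault("gamma", "scale")
        return Pipeline(
            [("scale", StandardScaler()), ("clf", SVC(kernel="rbf", random_state=spec.seed, **hp))]
        )
    if spec.kind == "random_forest":
        hp.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=spec.seed, **hp)
    hp.setdefault("shrinkage", None)
    return Pipeline(
        [("scale", StandardScaler()), ("clf", LinearDiscriminantAnalysis(**hp))]
    )


@dataclass
class PredictionTimeline:
    """Per-frame WM/OM prediction for one recording plus the raw window votes."""

    recording_id: str
    fps: float
    frame_pred: np.ndarray  # bool, True = WM
    window_preds: list[tuple[float, str]]  # (window_start_s, "WM"|"OM")


def aggregate_votes(
    window_preds: Sequence[tuple[float, str]],
    length_s: float,
    fps: float,
    n_frames: int,
    recording_id: str = "",
) -> PredictionTimeline:
    """Majority vote of all windows covering each frame; ties and gaps → OM.

    A window starting at ``s`` covers frames f with s <= f/fps < s+length.
    """
    wm = np.zeros(n_frames, dtype=int)
    om = np.zeros(n_frames, dtype=int)
    wlen = int(round(length_s * fps))
    for start_s, label in window_preds:
        i0 = int(round(start_s * fps))
        i1 = min(i0 + wlen, n_frames)
        if i0 >= n_frames or label not in ("WM", "OM"):
            raise ValueError(f"bad window prediction ({start_s}, {label!r})")
        (wm if label == "WM" else om)[i0:i1] += 1
    return PredictionTimeline(recording_id, fps, wm > om, list(window_preds))


# ---------------------------------------------------------------------------
# Dataset assembly and cross-validation
# ---------------------------------------------------------------------------

def assemble_dataset(
    features: Sequence[FrameFeatures], labels: Sequence[WindowLabel]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align window features with window labels into (X, y, window_starts).

    Features and labels must lie on the same window grid; windows flagged
    invalid are dropped. ``y`` is boolean (True = WM).
    """
    if len(features) != len(labels):
        raise ValueError(
            f"feature/label window counts differ: {len(features)} vs {len(labels)}"
        )
    for f, lab in zip(features, labels):
        if abs(f.window_start_s - lab.window_start_s) > 1e-9:
            raise ValueError(
                f"window grid mismatch at feature window {f.window_start_s} "
                f"vs label window {lab.window_start_s}"
            )
    keep = [i for i, f in enumerate(features) if f.valid]
    if not keep:
        raise ValueError("no valid windows left after filtering")
    X = np.stack([features[i].features for i in keep])
    y = np.array([labels[i].label == "WM" for i in keep])
    starts = np.array([features[i].window_start_s for i in keep])
    return X, y, starts


@dataclass
class RecordingWindows:
    """Everything LOOCV needs about one recording."""

    recording_id: str
    X: np.ndarray  # (n_valid_windows, 16)
    y: np.ndarray  # bool window labels
    window_starts: np.ndarray  # seconds, valid windows
    invalid_starts: np.ndarray  # seconds, windows dropped as invalid
    fps: float
    n_frames: int
    frame_truth: np.ndarray  # bool consensus labels per frame


def prepare_recording(
    features: Sequence[FrameFeatures],
    labels: Sequence[WindowLabel],
    truth: ConsensusLabels,
    n_frames: int,
) -> RecordingWindows:
    """Bundle one recording's windows, labels and frame truth for LOOCV."""
    X, y, starts = assemble_dataset(features, labels)
    invalid = np.array([f.window_start_s for f in features if not f.valid])
    return RecordingWindows(
        recording_id=truth.recording_id,
        X=X,
        y=y,
        window_starts=starts,
        invalid_starts=invalid,
        fps=truth.fps,
        n_frames=n_frames,
        frame_truth=np.asarray(truth.frame_labels, bool),
    )


@dataclass
class LoocvResult:
    """Leave-one-recording-out outcome: timelines plus pooled frame metrics."""

    timelines: dict[str, PredictionTimeline]
    pooled_metrics: dict[str, float]  # ACC/SENS/SPEC/F1, percent, WM positive
    pooled_counts: evaluation.ConfusionCounts
    wm_percentages: dict[str, float]  # per recording, from the timelines


def loocv(
    recordings: Sequence[RecordingWindows],
    spec: DetectorSpec,
    window: WindowSpec,
) -> LoocvResult:
    """Recording-level leave-one-out cross-validation of a detector.

    For each recording, the detector is fitted on all valid windows of the
    other recordings and predicts the held-out recording's windows; window
    predictions (plus invalid windows, voted OM) aggregate to a frame
    timeline. Frame confusions pool over all recordings with WM positive.
    """
    if len(recordings) < 2:
        raise ValueError("LOOCV needs at least 2 recordings")
    ids = [r.recording_id for r in recordings]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate recording ids")
    timelines: dict[str, PredictionTimeline] = {}
    for i, rec in enumerate(sorted(recordings, key=lambda r: r.recording_id)):
        train = [r for r in recordings if r.recording_id != rec.recording_id]
        X = np.concatenate([r.X for r in train])
        y = np.concatenate([r.y for r in train])
        if y.all() or not y.any():
            raise ValueError(
                "training fold has a single class; try a different consensus N "
                "or window labeling threshold"
            )
        clf = make_detector(spec)
        clf.fit(X, y)
        pred = clf.predict(rec.X).astype(bool)
        window_preds = [
            (float(s), "WM" if p else "OM") for s, p in zip(rec.window_starts, pred)
        ]
        window_preds += [(float(s), "OM") for s in rec.invalid_starts]
        window_preds.sort()
        timelines[rec.recording_id] = aggregate_votes(
            window_preds, window.length_s, rec.fps, rec.n_frames, rec.recording_id
        )
    pred_all = np.concatenate(
        [timelines[r.recording_id].frame_pred for r in recordings]
    )
    truth_all = np.concatenate([r.frame_truth for r in recordings])
    counts = evaluation.ConfusionCounts.from_arrays(pred_all, truth_all)
    wm_pct = {
        rid: evaluation.wm_percentage(tl.frame_pred) for rid, tl in timelines.items()
    }
    return LoocvResult(timelines, evaluation.metrics_from_counts(counts), counts, wm_pct)


#: Column order of the 16-feature training matrix (re-exported for callers).
TRAINING_COLUMNS = FEATURE_COLUMNS
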