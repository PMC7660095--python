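"""Reading, writing and validation of pose keypoint sequences and annotations.

The package operates on 2-D pose-estimator output in the 25-landmark BODY_25
layout: per frame, 25 (x, y, confidence) triplets in image-plane pixels
(origin top-left, y increasing downward). Two on-disk dialects are supported —
a directory of OpenPose-style per-frame JSON files, and a single delimited
table (long or wide form) — plus a CSV of expert-annotated writhing-movement
intervals. Both keypoint readers canonicalize into the same in-memory model,
:class:`KeypointSequence`, so everything downstream is format-agnostic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("writhekit")

N_LANDMARKS = 25

#: Named indices into the BODY_25 layout. Slots 15-24 (eyes, ears, feet) are
#: carried through I/O but unused by the feature pipeline.
BODY25: dict[str, int] = {
    "nose": 0,
    "neck": 1,
    "r_shoulder": 2,
    "r_elbow": 3,
    "r_wrist": 4,
    "l_shoulder": 5,
    "l_elbow": 6,
    "l_wrist": 7,
    "mid_hip": 8,
    "r_hip": 9,
    "r_knee": 10,
    "r_ankle": 11,
    "l_hip": 12,
    "l_knee": 13,
    "l_ankle": 14,
}


class PoseFormatError(ValueError):
    """Malformed or inconsistent keypoint input."""


class AnnotationError(ValueError):
    """Invalid expert-annotation input."""


@dataclass
class KeypointSequence:
    """One recording's keypoint time series.

    Attributes
    ----------
    recording_id : str
    fps : float
        Constant frame rate, frames/second, > 0.
    xy : ndarray, shape (n_frames, 25, 2)
        Pixel coordinates. A landmark whose confidence is 0 has undefined
        coordinates and must not be used before gap filling.
    conf : ndarray, shape (n_frames, 25)
        Detection confidences in [0, 1].
    invalid : ndarray of bool, shape (25,)
        Landmarks with no usable detection anywhere in the recording
        (set by gap filling; all False on fresh reads).
    """

    recording_id: str
    fps: float
    xy: np.ndarray
    conf: np.ndarray
    invalid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.conf = np.asarray(self.conf, dtype=float)
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.xy.ndim != 3 or self.xy.shape[1:] != (N_LANDMARKS, 2):
            raise PoseFormatError(
                f"xy must have shape (n_frames, {N_LANDMARKS}, 2), got {self.xy.shape}"
            )
        if self.conf.shape != self.xy.shape[:2]:
            raise PoseFormatError("conf shape must match xy frames/landmarks")
        if np.any(self.conf < -1e-9) or np.any(self.conf > 1 + 1e-9):
            raise PoseFormatError("confidences must lie in [0, 1]")
        if self.invalid is None:
            self.invalid = np.zeros(N_LANDMARKS, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def copy(self) -> "KeypointSequence":
        return replace(
            self, xy=self.xy.copy(), conf=self.conf.copy(), invalid=self.invalid.copy()
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KeypointSequence):
            return NotImplemented
        return (
            self.recording_id == other.recording_id
            and self.fps == other.fps
            and np.array_equal(self.xy, other.xy)
            and np.array_equal(self.conf, other.conf)
        )


@dataclass(frozen=True)
class ExpertIntervals:
    """One expert's writhing-movement intervals for one recording.

    Intervals are half-open ``[start_s, end_s)`` in seconds; frame ``f`` is
    inside iff ``start <= f/fps < end``. Overlapping or adjacent intervals are
    merged on construction, so the stored list is sorted and disjoint.
    """

    recording_id: str
    expert_id: str
    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for s, e in self.intervals:
            if not (0 <= s < e):
                raise AnnotationError(
                    f"invalid interval [{s}, {e}) for {self.recording_id}/{self.expert_id}"
                )
        object.__setattr__(self, "intervals", merge_intervals(self.intervals))

    @property
    def total_s(self) -> float:
        return sum(e - s for s, e in self.intervals)


def merge_intervals(
    intervals: Iterable[tuple[float, float]],
) -> tuple[tuple[float, float], ...]:
    """Sort and merge overlapping or touching half-open intervals."""
    ivs = sorted(intervals)
    merged: list[list[float]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


# ---------------------------------------------------------------------------
# OpenPose-style per-frame JSON
# ---------------------------------------------------------------------------

def _frame_from_json(path: Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise PoseFormatError(f"malformed JSON in {path}: {exc}") from exc
    people = doc.get("people", [])
    if not people:
        # no detection: all-zero confidence, coordinates undefined (zeros)
        return np.zeros((N_LANDMARKS, 2)), np.zeros(N_LANDMARKS)
    if len(people) > 1:
        logger.warning("%s: %d people detected, taking the first", path.name, len(people))
    person = people[0]
    flat = person.get("pose_keypoints_2d", person) if isinstance(person, dict) else person
    flat = np.asarray(flat, dtype=float)
    if flat.shape != (3 * N_LANDMARKS,):
        raise PoseFormatError(
            f"{path}: expected {3 * N_LANDMARKS} keypoint numbers, got {flat.size}"
        )
    triplets = flat.reshape(N_LANDMARKS, 3)
    return triplets[:, :2], triplets[:, 2]


def read_pose_json_dir(
    path: str | Path, recording_id: str | None = None, fps: float = 60.0
) -> KeypointSequence:
    """Read a directory of per-frame OpenPose JSON files.

    File names must sort in frame order (the usual zero-padded OpenPose
    naming). Each file holds a ``people`` array whose first entry is either a
    dict with ``pose_keypoints_2d`` or a bare flat list of 75 numbers. An
    empty ``people`` array yields a frame with all confidences 0.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix == ".json")
    if not files:
        raise PoseFormatError(f"no .json files in {path}")
    frames = [_frame_from_json(p) for p in files]
    xy = np.stack([f[0] for f in frames])
    conf = np.stack([f[1] for f in frames])
    return KeypointSequence(recording_id or path.name, fps, xy, conf)


# ---------------------------------------------------------------------------
# Delimited keypoint tables (long and wide form)
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ["frame", "landmark", "x", "y", "confidence"]


def _read_delimited(path: Path) -> pd.DataFrame:
    """CSV/TSV reader: sniffed delimiter, bit-exact float parsing."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def _wide_columns() -> list[str]:
    cols = ["frame"]
    for j in range(N_LANDMARKS):
        cols += [f"x{j}", f"y{j}", f"c{j}"]
    return cols


def _check_contiguous(frames: np.ndarray) -> None:
    uniq = np.unique(frames)
    expected = np.arange(uniq.size)
    if uniq.size == 0 or not np.array_equal(uniq, expected):
        missing = int(np.setdiff1d(np.arange(uniq.max() + 1 if uniq.size else 1), uniq)[0])
        raise PoseFormatError(f"frame indices not contiguous from 0: first missing index {missing}")


def read_pose_table(
    path: str | Path, recording_id: str | None = None, fps: float = 60.0
) -> KeypointSequence:
    """Read a delimited keypoint table (CSV/TSV, long or wide form).

    The dialect is auto-detected from the header: long form has columns
    ``frame, landmark, x, y, confidence``; wide form has ``frame`` plus
    ``x0, y0, c0 … x24, y24, c24``.
    """
    path = Path(path)
    df = _read_delimited(path)
    cols = set(df.columns)
    if set(_LONG_COLUMNS) <= cols:
        frames = df["frame"].to_numpy(int)
        _check_contiguous(frames)
        n = frames.max() + 1
        xy = np.zeros((n, N_LANDMARKS, 2))
        conf = np.zeros((n, N_LANDMARKS))
        lm = df["landmark"].to_numpy(int)
        if lm.min() < 0 or lm.max() >= N_LANDMARKS:
            raise PoseFormatError("landmark indices must be in [0, 24]")
        xy[frames, lm, 0] = df["x"].to_numpy(float)
        xy[frames, lm, 1] = df["y"].to_numpy(float)
        conf[frames, lm] = df["confidence"].to_numpy(float)
    elif "frame" in cols and {"x0", "y0", "c0"} <= cols:
        missing = [c for c in _wide_columns() if c not in cols]
        if missing:
            raise PoseFormatError(f"wide table missing columns: {missing}")
        df = df.sort_values("frame")
        frames = df["frame"].to_numpy(int)
        _check_contiguous(frames)
        xy = np.zeros((len(df), N_LANDMARKS, 2))
        conf = np.zeros((len(df), N_LANDMARKS))
        for j in range(N_LANDMARKS):
            xy[:, j, 0] = df[f"x{j}"].to_numpy(float)
            xy[:, j, 1] = df[f"y{j}"].to_numpy(float)
            conf[:, j] = df[f"c{j}"].to_numpy(float)
    else:
        missing = [c for c in _LONG_COLUMNS if c not in cols]
        raise PoseFormatError(
            f"unrecognized keypoint table header; long form is missing columns {missing}"
        )
    return KeypointSequence(recording_id or path.stem, fps, xy, conf)


def write_pose_table(
    seq: KeypointSequence, path: str | Path, form: str = "long"
) -> None:
    """Write a sequence as a delimited table readable by :func:`read_pose_table`."""
    path = Path(path)
    if form == "long":
        n, k = seq.n_frames, N_LANDMARKS
        df = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n), k),
                "landmark": np.tile(np.arange(k), n),
                "x": seq.xy[:, :, 0].ravel(),
                "y": seq.xy[:, :, 1].ravel(),
                "confidence": seq.conf.ravel(),
            }
        )
    elif form == "wide":
        data: dict[str, np.ndarray] = {"frame": np.arange(seq.n_frames)}
        for j in range(N_LANDMARKS):
            data[f"x{j}"] = seq.xy[:, j, 0]
            data[f"y{j}"] = seq.xy[:, j, 1]
            data[f"c{j}"] = seq.conf[:, j]
        df = pd.DataFrame(data)
    else:
        raise ValueError("form must be 'long' or 'wide'")
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Expert annotations
# ---------------------------------------------------------------------------

_ANN_COLUMNS = ["recording_id", "expert_id", "start_s", "end_s"]


def read_annotations(path: str | Path) -> list[ExpertIntervals]:
    """Read an annotation CSV (recording_id, expert_id, start_s, end_s).

    Per (recording, expert), overlapping or touching intervals are merged.
    A row with start >= end raises :class:`AnnotationError` with its row
    number (1-based, excluding the header).
    """
    df = _read_delimited(Path(path))
    missing = [c for c in _ANN_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"annotation file missing columns: {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if not (0 <= row.start_s < row.end_s):
            raise AnnotationError(
                f"row {i}: invalid interval [{row.start_s}, {row.end_s})"
            )
    out: list[ExpertIntervals] = []
    for (rec, exp), grp in df.groupby(["recording_id", "expert_id"], sort=True):
        ivs = tuple(zip(grp["start_s"].astype(float), grp["end_s"].astype(float)))
        out.append(ExpertIntervals(str(rec), str(exp), ivs))
    return out


def write_annotations(annotations: Sequence[ExpertIntervals], path: str | Path) -> None:
    rows = [
        {"recording_id": a.recording_id, "expert_id": a.expert_id, "start_s": s, "end_s": e}
        for a in annotations
        for s, e in a.intervals
    ]
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(path, index=False, float_format="%.17g")
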