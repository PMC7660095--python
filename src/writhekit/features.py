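"""Ellipse-based limb-movement features on windowed distal trajectories.

Writhing movements trace roughly elliptical paths with the distal parts of
the limbs (wrists, ankles). Within each analysis window the trajectory of
each distal landmark is cleaned (IQR outlier pass, radius downsampling), an
ellipse is circumscribed on it via the eigendecomposition of the coordinate
covariance matrix, and three limb-length-normalized descriptors are derived:

* **FMA** (factor of movement's area): ellipse area over the area of the
  circle of radius L (the limb length) — the fraction of the reachable range
  actually swept, ``a·b / L²``.
* **FMS** (factor of movement's shape): minor/major axis ratio ``b/a`` —
  1 for circular motion, 0 for purely linear motion.
* **CMA** (center of movement's area): the ellipse center in a coordinate
  system anchored at the proximal joint (shoulder or hip) with unit L,
  vertical component positive toward the head and horizontal component
  positive away from the body axis (distal direction).

Four limbs × (FMA, FMS, CMA-h, CMA-v) concatenate to a 16-feature vector per
window. All features are dimensionless, so they are invariant to image scale
and — after the preprocessing normalization — to the infant's position and
orientation in the image.

The ellipse scale is fixed at ``semi_axis = sqrt(2·eigenvalue)``: with that
convention, uniform sampling of an ellipse perimeter is recovered exactly
(Var of a·cos θ over a full revolution is a²/2), so FMA = 1 means the full
reachable circle was swept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pose_io import BODY25, KeypointSequence

logger = logging.getLogger("writhekit")

#: Fixed limb order of the 16-feature vector.
LIMBS: tuple[str, ...] = ("r_arm", "l_arm", "r_leg", "l_leg")

#: (proximal, middle, distal) joints of each limb.
LIMB_JOINTS: dict[str, tuple[str, str, str]] = {
    "r_arm": ("r_shoulder", "r_elbow", "r_wrist"),
    "l_arm": ("l_shoulder", "l_elbow", "l_wrist"),
    "r_leg": ("r_hip", "r_knee", "r_ankle"),
    "l_leg": ("l_hip", "l_knee", "l_ankle"),
}

_PER_LIMB = ("fma", "fms", "cma_h", "cma_v")

#: Column names of the 16-feature vector, in order.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{limb}_{feat}" for limb in LIMBS for feat in _PER_LIMB
)

#: Minimum trajectory size for the IQR outlier pass (quartiles of fewer
#: points are too unstable to define outliers).
MIN_POINTS_FOR_OUTLIER_FILTER = 8


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: length and overlap in seconds.

    The window grid is anchored at t = 0 with stride ``length_s −
    overlap_s``; a trailing partial window is dropped.
    """

    length_s: float = 15.0
    overlap_s: float = 10.0

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_s < self.length_s):
            raise ValueError("require 0 <= overlap_s < length_s")

    @property
    def step_s(self) -> float:
        return self.length_s - self.overlap_s

    def frame_windows(self, n_frames: int, fps: float) -> list[tuple[int, int]]:
        """(start, stop) frame slices of every complete window."""
        wlen = int(round(self.length_s * fps))
        wstep = int(round(self.step_s * fps))
        out = []
        i0 = 0
        while i0 + wlen <= n_frames:
            out.append((i0, i0 + wlen))
            i0 += wstep
        return out


@dataclass(frozen=True)
class EllipseFit:
    """Ellipse circumscribed on a trajectory: centroid, semi-axes, orientation."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float  # radians of the major axis, in (-pi/2, pi/2]

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor >= 0):
            raise ValueError("require semi_major >= semi_minor >= 0")


@dataclass(frozen=True)
class LimbFeatureVector:
    """FMA, FMS and CMA components for one limb and window."""

    fma: float
    fms: float
    cma_h: float
    cma_v: float
    valid: bool = True

    def as_array(self) -> np.ndarray:
        return np.array([self.fma, self.fms, self.cma_h, self.cma_v])


INVALID_LIMB = LimbFeatureVector(np.nan, np.nan, np.nan, np.nan, valid=False)


@dataclass(frozen=True)
class FrameFeatures:
    """The 16-feature vector of one analysis window."""

    recording_id: str
    window_start_s: float
    features: np.ndarray  # shape (16,), order FEATURE_COLUMNS
    valid: bool


# ---------------------------------------------------------------------------
# Trajectory cleaning
# ---------------------------------------------------------------------------

def remove_outliers(points: np.ndarray) -> np.ndarray:
    """Single-pass IQR outlier deletion on distances from the centroid.

    The centroid is the coordinate-wise mean of *all* input points; points
    whose Euclidean distance from it exceeds Q3 + 1.5·IQR (quartiles by
    linear interpolation) are removed in one non-iterative pass. Inputs with
    fewer than 8 points are returned unchanged.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < MIN_POINTS_FOR_OUTLIER_FILTER:
        return points
    centroid = points.mean(axis=0)
    d = np.hypot(points[:, 0] - centroid[0], points[:, 1] - centroid[1])
    q1, q3 = np.percentile(d, [25, 75])
    cutoff = q3 + 1.5 * (q3 - q1)
    # relative slack so constant-distance trajectories (IQR ~ 0 up to
    # rounding, e.g. a perfect circle) are not clipped by float noise
    return points[d <= cutoff * (1 + 1e-9)]


def downsample(points: np.ndarray, epsilon: float) -> np.ndarray:
    """Sequential radius thinning of a trajectory.

    Keeps the first point, then each subsequent point only if its Euclidean
    distance from the last *kept* point is >= ``epsilon``; order preserved.
    This removes the pile-up of near-identical points where the limb stops,
    which would otherwise over-weight rest positions in the covariance.
    ``epsilon = 0`` is the identity.
    """
    points = np.asarray(points, dtype=float)
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if epsilon == 0 or len(points) == 0:
        return points.copy()
    keep = [0]
    last = points[0]
    eps2 = epsilon * epsilon
    for i in range(1, len(points)):
        dx = points[i, 0] - last[0]
        dy = points[i, 1] - last[1]
        if dx * dx + dy * dy >= eps2:
            keep.append(i)
            last = points[i]
    return points[keep]


# ---------------------------------------------------------------------------
# Ellipse fit and per-limb features
# ---------------------------------------------------------------------------

def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Circumscribe an ellipse via covariance eigendecomposition.

    center = centroid of the points; semi-axes = sqrt(2·eigenvalue) of the
    (population) covariance matrix, major >= minor; orientation = angle of
    the major-axis eigenvector, normalized to (-pi/2, pi/2]. Degenerate
    inputs are allowed: a single point gives both axes 0, collinear points
    give semi_minor 0 with the orientation along the segment.
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise ValueError("cannot fit an ellipse to an empty trajectory")
    center = points.mean(axis=0)
    if len(points) == 1:
        return EllipseFit((center[0], center[1]), 0.0, 0.0, 0.0)
    cov = np.cov(points.T, bias=True)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals = np.clip(evals, 0.0, None)
    major_vec = evecs[:, 1]
    angle = float(np.arctan2(major_vec[1], major_vec[0]))
    if angle <= -np.pi / 2:
        angle += np.pi
    elif angle > np.pi / 2:
        angle -= np.pi
    return EllipseFit(
        (float(center[0]), float(center[1])),
        float(np.sqrt(2.0 * evals[1])),
        float(np.sqrt(2.0 * evals[0])),
        angle,
    )


def limb_length(seq: KeypointSequence, limb: str) -> float:
    """Limb length in pixels: max over frames of the two-segment arc length.

    Per frame, the Euclidean distances proximal–middle and middle–distal are
    summed (e.g. shoulder–elbow + elbow–wrist); the maximum over the
    recording is returned, corresponding to the frame where the limb lies
    most nearly parallel to the image plane. If the limb is bent in every
    frame this is a lower-bound estimate of the true length. Returns NaN if
    any of the three landmarks is invalid for the whole recording.
    """
    names = LIMB_JOINTS[limb]
    idx = [BODY25[n] for n in names]
    if seq.invalid[idx].any():
        return float("nan")
    p, m, d = (seq.xy[:, i] for i in idx)
    lengths = np.hypot(*(m - p).T) + np.hypot(*(d - m).T)
    return float(lengths.max())


def limb_lengths(seq: KeypointSequence) -> dict[str, float]:
    """Limb length of all four limbs, measured once per recording."""
    return {limb: limb_length(seq, limb) for limb in LIMBS}


def limb_features(
    fit: EllipseFit,
    L: float,
    proximal_joint: tuple[float, float],
    body_axis_x: float,
    distal_positive: bool = True,
) -> LimbFeatureVector:
    """Normalize an ellipse fit into the FMA/FMS/CMA descriptor.

    Inputs must be in the anchored, head-up frame (y decreases toward the
    head). ``proximal_joint`` is the window-mean position of the shoulder
    (arms) or hip (legs); ``body_axis_x`` locates the trunk axis so the
    horizontal CMA sign can point away from it (``distal_positive=False``
    flips that convention toward the body axis).
    """
    if not (L > 0) or not np.isfinite(L):
        return INVALID_LIMB
    a, b = fit.semi_major, fit.semi_minor
    fma = a * b / (L * L)
    fms = b / a if a > 0 else 0.0
    px, py = proximal_joint
    cx, cy = fit.center
    cma_v = (py - cy) / L  # y shrinks toward the head => positive head-ward
    sign = 1.0 if px > body_axis_x else -1.0
    if not distal_positive:
        sign = -sign
    cma_h = sign * (cx - px) / L
    return LimbFeatureVector(float(fma), float(fms), float(cma_h), float(cma_v))


# ---------------------------------------------------------------------------
# Windowed extraction
# ---------------------------------------------------------------------------

def extract_windows(
    seq: KeypointSequence,
    spec: WindowSpec,
    lengths: Mapping[str, float] | None = None,
    epsilon_frac: float = 0.005,
    distal_positive: bool = True,
) -> list[FrameFeatures]:
    """Slide the window grid over a preprocessed recording and featurize.

    Per window and limb: slice the distal trajectory → IQR outlier pass →
    radius downsampling (ε = ``epsilon_frac``·L) → ellipse fit → FMA/FMS/CMA.
    Limb lengths are measured once on the full recording unless supplied.
    Windows where any limb is invalid are emitted with ``valid=False``. A
    recording shorter than one window yields an empty list with a warning.
    """
    windows = spec.frame_windows(seq.n_frames, seq.fps)
    if not windows:
        logger.warning(
            "recording %s (%.1f s) shorter than one %g s window; no features",
            seq.recording_id,
            seq.duration_s,
            spec.length_s,
        )
        return []
    L = dict(lengths) if lengths is not None else limb_lengths(seq)
    neck = BODY25["neck"]
    out: list[FrameFeatures] = []
    for i0, i1 in windows:
        start_s = i0 / seq.fps
        body_axis_x = float(seq.xy[i0:i1, neck, 0].mean())
        vec = np.full(16, np.nan)
        valid = True
        for k, limb in enumerate(LIMBS):
            names = LIMB_JOINTS[limb]
            idx = [BODY25[n] for n in names]
            Lk = L.get(limb, float("nan"))
            if seq.invalid[idx].any() or not (Lk > 0) or not np.isfinite(Lk):
                valid = False
                continue
            traj = seq.xy[i0:i1, idx[2]]
            clean = downsample(remove_outliers(traj), epsilon_frac * Lk)
            fit = fit_ellipse(clean)
            prox = seq.xy[i0:i1, idx[0]].mean(axis=0)
            lf = limb_features(fit, Lk, (prox[0], prox[1]), body_axis_x, distal_positive)
            if not lf.valid:
                valid = False
                continue
            vec[4 * k : 4 * (k + 1)] = lf.as_array()  # noqa: E203
        out.append(FrameFeatures(seq.recording_id, start_s, vec, valid))
    return out


def features_table(features: Sequence[FrameFeatures]) -> pd.DataFrame:
    """Tabulate window features: recording_id, window_start_s, 16 columns, valid."""
    rows = []
    for f in features:
        row: dict[str, object] = {
            "recording_id": f.recording_id,
            "window_start_s": f.window_start_s,
        }
        row.update(zip(FEATURE_COLUMNS, f.features))
        row["valid"] = f.valid
        rows.append(row)
    cols = ["recording_id", "window_start_s", *FEATURE_COLUMNS, "valid"]
    return pd.DataFrame(rows, columns=cols)
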