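"""Keypoint cleaning and normalization.

Pose-estimator output carries three artefacts that must be removed before any
geometric feature makes sense: frames where a landmark was not detected
(low confidence), high-frequency detection jitter, and the arbitrary position
and orientation of the infant in the image. The pipeline here is

    fill_low_confidence  →  smooth (Savitzky–Golay)  →  anchor_and_rotate

after which every recording sits in a common body frame: the neck pinned at a
fixed reference point and the neck→mid-hip axis pointing straight down the
image (+y), i.e. head up. All downstream features assume this frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .pose_io import BODY25, KeypointSequence


class PreprocessError(RuntimeError):
    """Unrecoverable preprocessing failure (e.g. no usable body axis)."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the cleaning pipeline.

    confidence_threshold : detections below it are treated as missing.
    sg_window, sg_polyorder : Savitzky–Golay filter (window in frames, odd).
        Defaults (31 frames ≈ 0.5 s at 60 fps, cubic) suppress per-frame
        detection jitter while preserving sub-second limb motion.
    """

    confidence_threshold: float = 0.3
    sg_window: int = 31
    sg_polyorder: int = 3
    anchor_landmark: str = "neck"
    axis_landmarks: tuple[str, str] = ("neck", "mid_hip")

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if not (1 <= self.sg_polyorder < self.sg_window):
            raise ValueError("require 1 <= sg_polyorder < sg_window")
        if not (0 <= self.confidence_threshold <= 1):
            raise ValueError("confidence_threshold must lie in [0, 1]")


def fill_low_confidence(seq: KeypointSequence, threshold: float = 0.3) -> KeypointSequence:
    """Replace low-confidence detections by the last confident position.

    Every landmark position with confidence < ``threshold`` is replaced by
    that landmark's most recent position with confidence >= threshold; leading
    low-confidence frames are back-filled from the first valid position. A
    landmark with no valid position anywhere is flagged in ``invalid`` and
    must not be used downstream. Confidences are left untouched so the
    operation is auditable.
    """
    xy = seq.xy.copy()
    invalid = seq.invalid.copy()
    n = seq.n_frames
    idx = np.arange(n)
    for j in range(xy.shape[1]):
        valid = seq.conf[:, j] >= threshold
        if not valid.any():
            invalid[j] = True
            continue
        # index of the most recent valid frame at or before each frame
        last = np.where(valid, idx, -1)
        np.maximum.accumulate(last, out=last)
        first_valid = idx[valid][0]
        last[last < 0] = first_valid  # back-fill the leading gap
        xy[:, j] = xy[last, j]
    return replace(seq, xy=xy, conf=seq.conf.copy(), invalid=invalid)


def smooth(seq: KeypointSequence, window: int = 31, polyorder: int = 3) -> KeypointSequence:
    """Savitzky–Golay smoothing of every coordinate channel.

    Edges are handled by a polynomial fit on the truncated window
    (``mode="interp"``), so no invented padding values enter the result.
    """
    if window % 2 == 0 or polyorder >= window:
        raise ValueError("window must be odd and polyorder < window")
    if seq.n_frames < window:
        raise ValueError(
            f"sequence has {seq.n_frames} frames, shorter than the smoothing window "
            f"({window}); reduce sg_window"
        )
    xy = savgol_filter(seq.xy, window, polyorder, axis=0, mode="interp")
    return replace(seq, xy=xy, conf=seq.conf.copy(), invalid=seq.invalid.copy())


def anchor_and_rotate(
    seq: KeypointSequence,
    anchor: str = "neck",
    axis: tuple[str, str] = ("neck", "mid_hip"),
) -> KeypointSequence:
    """Pin the neck and align the body axis with the image +y direction.

    Per frame, all 25 points are translated so the anchor (neck) sits at a
    fixed reference — its position in frame 0 — and then rotated about it so
    the neck→mid-hip vector points in +y (head toward smaller y). This is a
    per-frame rigid motion, so all inter-landmark distances are preserved
    exactly, and the operation is idempotent: the output of a second
    application equals the first.
    """
    ia, i0, i1 = BODY25[anchor], BODY25[axis[0]], BODY25[axis[1]]
    if seq.invalid[ia] or seq.invalid[i0] or seq.invalid[i1]:
        raise PreprocessError(
            f"cannot anchor: landmark(s) {anchor}/{axis[0]}/{axis[1]} invalid "
            f"for recording {seq.recording_id}"
        )
    v = seq.xy[:, i1] - seq.xy[:, i0]
    norms = np.hypot(v[:, 0], v[:, 1])
    if np.any(norms == 0):
        raise PreprocessError(
            f"degenerate body axis (coincident {axis[0]}/{axis[1]}) in recording "
            f"{seq.recording_id}"
        )
    ref = seq.xy[0, ia].copy()
    phi = np.pi / 2 - np.arctan2(v[:, 1], v[:, 0])  # rotate axis onto +y
    c, s = np.cos(phi), np.sin(phi)
    rel = seq.xy - seq.xy[:, ia : ia + 1]  # noqa: E203
    x = c[:, None] * rel[:, :, 0] - s[:, None] * rel[:, :, 1]
    y = s[:, None] * rel[:, :, 0] + c[:, None] * rel[:, :, 1]
    xy = np.stack([x, y], axis=2) + ref
    return replace(seq, xy=xy, conf=seq.conf.copy(), invalid=seq.invalid.copy())


def preprocess_sequence(
    seq: KeypointSequence, cfg: PreprocessConfig | None = None
) -> KeypointSequence:
    """Run the full cleaning pipeline: fill → smooth → anchor/rotate."""
    cfg = cfg or PreprocessConfig()
    out = fill_low_confidence(seq, cfg.confidence_threshold)
    out = smooth(out, cfg.sg_window, cfg.sg_polyorder)
    return anchor_and_rotate(out, cfg.anchor_landmark, cfg.axis_landmarks)
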