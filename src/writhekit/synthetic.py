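"""Synthetic keypoint recordings and simulated expert annotations.

Every stage of the pipeline is testable without clinical data: this module
generates BODY_25 keypoint sequences with known ground truth. The infant is
emulated as a quasi-static trunk (per-frame Gaussian jitter) with each distal
landmark (wrist/ankle) tracing a parametric ellipse around a rest center near
its proximal joint — writhing movements are elliptical by nature, which is
exactly what the feature set is built to capture. Two movement regimes are
distinguished:

* ``wm`` — moderate elliptical motion, default semi-axes (0.35·L, 0.20·L);
* ``om`` — small monotonous motion, default semi-axes (0.06·L, 0.05·L),
  emulating rest or poor-repertoire-like movement.

Intermediate joints (elbow/knee) are placed by two-link inverse kinematics
with fixed segment lengths, so the limb-length measurement of the feature
module recovers the configured L. Detection jitter (σ = 0.01·L by default)
and confidence dropouts (2%) emulate pose-estimator noise. Simulated experts
reproduce the boundary disagreement of human raters: each expert's intervals
are the true regime intervals with Gaussian-jittered endpoints.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .pose_io import BODY25, N_LANDMARKS, ExpertIntervals, KeypointSequence

#: Quasi-static base pose, pixels, head up (smaller y), 1920×1080-ish frame.
BASE_POSE: dict[str, tuple[float, float]] = {
    "nose": (960.0, 290.0),
    "neck": (960.0, 350.0),
    "r_shoulder": (870.0, 370.0),
    "l_shoulder": (1050.0, 370.0),
    "mid_hip": (960.0, 610.0),
    "r_hip": (905.0, 610.0),
    "l_hip": (1015.0, 610.0),
}

#: (proximal-middle, middle-distal) segment lengths in pixels.
SEGMENTS: dict[str, tuple[float, float]] = {
    "r_arm": (100.0, 110.0),
    "l_arm": (100.0, 110.0),
    "r_leg": (120.0, 130.0),
    "l_leg": (120.0, 130.0),
}

_LIMB_JOINTS = {
    "r_arm": ("r_shoulder", "r_elbow", "r_wrist"),
    "l_arm": ("l_shoulder", "l_elbow", "l_wrist"),
    "r_leg": ("r_hip", "r_knee", "r_ankle"),
    "l_leg": ("l_hip", "l_knee", "l_ankle"),
}

#: Rest-center offset of the distal landmark from its proximal joint, as
#: fractions of L; the lateral component points away from the body axis.
_CENTER_OFFSET = {"arm": (0.25, 0.30), "leg": (0.20, 0.45)}


@dataclass(frozen=True)
class Regime:
    """One movement regime interval: kind ``wm`` or ``om``, seconds."""

    kind: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.kind not in ("wm", "om"):
            raise ValueError("regime kind must be 'wm' or 'om'")
        if not (0 <= self.start_s < self.end_s):
            raise ValueError("require 0 <= start_s < end_s")


@dataclass(frozen=True)
class LimbEllipse:
    """Generating ellipse of one limb over one regime interval."""

    limb: str
    start_s: float
    end_s: float
    a: float  # semi-major, pixels
    b: float  # semi-minor, pixels
    center: tuple[float, float]  # absolute pixels
    phi: float  # orientation, radians
    omega: float  # angular velocity, rad/s
    phase: float


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one simulated recording.

    Defaults are the package's fixed study conditions: 60 fps camera, 120 s
    recordings, wm/om ellipse axes (0.35, 0.20)/(0.06, 0.05)·L, trajectory
    jitter σ = 0.01·L, 2% confidence dropout, 5 experts with 0.5 s boundary
    jitter. ``regimes=None`` means a single wm regime spanning the recording.
    """

    seed: int = 0
    recording_id: str = "sim"
    fps: float = 60.0
    duration_s: float = 120.0
    regimes: tuple[Regime, ...] | None = None
    wm_axes: tuple[float, float] = (0.35, 0.20)
    om_axes: tuple[float, float] = (0.06, 0.05)
    axis_spread: float = 0.15  # uniform relative spread on the axes
    omega_wm: tuple[float, float] = (0.5, 1.0)  # rad/s
    omega_om: tuple[float, float] = (0.3, 0.8)
    jitter_frac: float = 0.01  # of L, Gaussian σ on distal trajectories
    trunk_jitter_px: float = 1.0
    dropout_rate: float = 0.02
    n_experts: int = 5
    expert_jitter_s: float = 0.5


@dataclass
class SimRecording:
    """A simulated recording with its ground truth."""

    seq: KeypointSequence
    truth_wm: list[tuple[float, float]]  # true WM intervals, seconds
    gen_params: list[LimbEllipse]
    config: SimConfig = field(repr=False, default=None)  # type: ignore[assignment]


def sample_ellipse_window(
    rng: np.random.Generator,
    L: float,
    n_points: int,
    a_frac: tuple[float, float] = (0.2, 0.45),
    jitter_frac: float = 0.01,
    center: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, float, float, float]:
    """Uniform-perimeter-parameter sample of a random ellipse plus jitter.

    Returns (points, a, b, phi): ``n_points`` positions at uniformly spaced
    parameter angles over full revolutions of an ellipse with semi-axes drawn
    as fractions of L (minor axis between 0.3·a and a), rotated by a random
    phi, centered at ``center``, with isotropic Gaussian jitter σ =
    ``jitter_frac``·L. Used for estimator-recovery checks.
    """
    a = L * rng.uniform(*a_frac)
    b = a * rng.uniform(0.3, 1.0)
    phi = rng.uniform(0, np.pi)
    theta = np.linspace(0, 2 * np.pi, n_points, endpoint=False) + rng.uniform(0, 2 * np.pi)
    pts = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
    c, s = np.cos(phi), np.sin(phi)
    pts = pts @ np.array([[c, s], [-s, c]])
    pts += np.asarray(center)
    pts += rng.normal(0, jitter_frac * L, pts.shape)
    return pts, a, b, phi


def alternating_regimes(
    duration_s: float,
    rng: np.random.Generator,
    first: str = "wm",
    dur_range: tuple[float, float] = (15.0, 30.0),
) -> tuple[Regime, ...]:
    """Tile the duration with alternating wm/om intervals of random length."""
    out: list[Regime] = []
    t = 0.0
    kind = first
    while t < duration_s:
        end = min(t + rng.uniform(*dur_range), duration_s)
        out.append(Regime(kind, t, end))
        kind = "om" if kind == "wm" else "wm"
        t = end
    return tuple(out)


def om_only_regimes(duration_s: float) -> tuple[Regime, ...]:
    return (Regime("om", 0.0, duration_s),)


def _ik_middle(
    prox: np.ndarray, dist: np.ndarray, l1: float, l2: float, bend: float
) -> np.ndarray:
    """Two-link inverse kinematics: middle joint with fixed segment lengths."""
    v = dist - prox
    d = np.hypot(v[:, 0], v[:, 1])
    d = np.maximum(d, 1e-9)
    u = v / d[:, None]
    a1 = (l1 * l1 - l2 * l2 + d * d) / (2 * d)
    h = np.sqrt(np.clip(l1 * l1 - a1 * a1, 0.0, None))
    perp = np.column_stack([-u[:, 1], u[:, 0]]) * bend
    return prox + a1[:, None] * u + h[:, None] * perp


def simulate_recording(cfg: SimConfig) -> SimRecording:
    """Generate one keypoint recording with known regime ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fps))
    t = np.arange(n) / cfg.fps
    regimes = cfg.regimes
    if regimes is None:
        regimes = (Regime("wm", 0.0, cfg.duration_s),)
    covered = sorted((r.start_s, r.end_s) for r in regimes)
    pos = 0.0
    for s, e in covered:
        if abs(s - pos) > 1e-9:
            raise ValueError("regime intervals must tile the duration without gaps")
        pos = e
    if abs(pos - cfg.duration_s) > 1e-9:
        raise ValueError("regime intervals must cover the full duration")

    xy = np.zeros((n, N_LANDMARKS, 2))
    conf = np.ones((n, N_LANDMARKS))

    for name, base in BASE_POSE.items():
        xy[:, BODY25[name]] = base + rng.normal(0, cfg.trunk_jitter_px, (n, 2))
    # unused face/foot slots: static clutter near the head
    for j in range(15, N_LANDMARKS):
        base = np.array(BASE_POSE["nose"]) + np.array([10.0 * (j - 19), -15.0])
        xy[:, j] = base + rng.normal(0, cfg.trunk_jitter_px, (n, 2))

    gen_params: list[LimbEllipse] = []
    for limb, (prox_name, mid_name, dist_name) in _LIMB_JOINTS.items():
        l1, l2 = SEGMENTS[limb]
        L = l1 + l2
        prox_base = np.array(BASE_POSE[prox_name])
        lateral = -1.0 if limb.startswith("r") else 1.0  # away from body axis
        off = _CENTER_OFFSET["arm" if limb.endswith("arm") else "leg"]
        center = prox_base + L * np.array([lateral * off[0], off[1]])
        dist = np.zeros((n, 2))
        for reg in regimes:
            i0 = int(round(reg.start_s * cfg.fps))
            i1 = int(round(reg.end_s * cfg.fps))
            base_a, base_b = cfg.wm_axes if reg.kind == "wm" else cfg.om_axes
            spread = cfg.axis_spread
            a = L * base_a * rng.uniform(1 - spread, 1 + spread)
            b = L * base_b * rng.uniform(1 - spread, 1 + spread)
            a, b = max(a, b), min(a, b)
            om_range = cfg.omega_wm if reg.kind == "wm" else cfg.omega_om
            omega = rng.uniform(*om_range)
            phi = rng.uniform(0, np.pi)
            phase = rng.uniform(0, 2 * np.pi)
            tt = t[i0:i1] - reg.start_s
            px = a * np.cos(omega * tt + phase)
            py = b * np.sin(omega * tt + phase)
            c, s = np.cos(phi), np.sin(phi)
            dist[i0:i1, 0] = center[0] + c * px - s * py
            dist[i0:i1, 1] = center[1] + s * px + c * py
            gen_params.append(
                LimbEllipse(
                    limb, reg.start_s, reg.end_s, a, b,
                    (center[0], center[1]), phi, omega, phase,
                )
            )
        dist += rng.normal(0, cfg.jitter_frac * L, (n, 2))
        # keep the wrist/ankle inside the kinematic reach of the two segments
        prox = xy[:, BODY25[prox_name]]
        v = dist - prox
        d = np.hypot(v[:, 0], v[:, 1])
        over = d > 0.98 * L
        if over.any():
            dist[over] = prox[over] + v[over] * (0.98 * L / d[over])[:, None]
        xy[:, BODY25[dist_name]] = dist
        xy[:, BODY25[mid_name]] = _ik_middle(prox, dist, l1, l2, bend=lateral)

    if cfg.dropout_rate > 0:
        drop = rng.random((n, N_LANDMARKS)) < cfg.dropout_rate
        conf[drop] = 0.0
        xy[drop] = 0.0  # undefined coordinates, must be gap-filled

    seq = KeypointSequence(cfg.recording_id, cfg.fps, xy, conf)
    truth = [(r.start_s, r.end_s) for r in regimes if r.kind == "wm"]
    return SimRecording(seq, truth, gen_params, cfg)


def simulate_experts(
    truth_wm: Sequence[tuple[float, float]],
    n_experts: int,
    jitter_s: float,
    duration_s: float,
    recording_id: str,
    rng: np.random.Generator | int,
) -> list[ExpertIntervals]:
    """Simulate K experts marking the true WM intervals with boundary jitter.

    Each expert perturbs every interval endpoint by centered Gaussian noise
    (clipped to the recording), independently; degenerate intervals are
    dropped. With ``jitter_s = 0`` every expert equals the truth.
    """
    if n_experts < 1:
        raise ValueError("need at least one expert")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = []
    for k in range(n_experts):
        ivs = []
        for s, e in truth_wm:
            s2 = float(np.clip(s + rng.normal(0, jitter_s), 0, duration_s))
            e2 = float(np.clip(e + rng.normal(0, jitter_s), 0, duration_s))
            if e2 > s2:
                ivs.append((s2, e2))
        out.append(ExpertIntervals(recording_id, f"E{k + 1}", tuple(ivs)))
    return out


@dataclass
class StudyRecording:
    """One recording of a simulated WM/PR study, with annotations."""

    recording_id: str
    group: str  # "WM" | "PR"
    seq: KeypointSequence
    truth_wm: list[tuple[float, float]]
    experts: list[ExpertIntervals]
    gen_params: list[LimbEllipse]


def simulate_study(
    n_wm: int = 15,
    n_om: int = 15,
    seed: int = 7,
    fps: float = 60.0,
    duration_s: float = 120.0,
    n_experts: int = 5,
    expert_jitter_s: float = 0.5,
    **overrides,
) -> list[StudyRecording]:
    """Simulate a two-group study: WM-rich recordings and om-only (PR) ones.

    WM-rich recordings alternate wm and om regimes with durations uniform in
    [15, 30] s; PR recordings contain only monotonous om motion, so their
    true WM content is zero and their simulated experts mark nothing. Fully
    reproducible from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_wm + n_om)
    out: list[StudyRecording] = []
    for i in range(n_wm + n_om):
        wm_rich = i < n_wm
        rid = f"wm{i + 1:02d}" if wm_rich else f"om{i - n_wm + 1:02d}"
        child = children[i]
        rec_seed, regime_seed, expert_seed = (
            int(s) % (2**31) for s in child.generate_state(3)
        )
        if wm_rich:
            regimes = alternating_regimes(
                duration_s, np.random.default_rng(regime_seed)
            )
        else:
            regimes = om_only_regimes(duration_s)
        cfg = SimConfig(
            seed=rec_seed,
            recording_id=rid,
            fps=fps,
            duration_s=duration_s,
            regimes=regimes,
            n_experts=n_experts,
            expert_jitter_s=expert_jitter_s,
            **overrides,
        )
        rec = simulate_recording(cfg)
        experts = simulate_experts(
            rec.truth_wm, n_experts, expert_jitter_s, duration_s, rid, expert_seed
        )
        out.append(
            StudyRecording(
                rid, "WM" if wm_rich else "PR", rec.seq, rec.truth_wm, experts,
                rec.gen_params,
            )
        )
    return out


def regenerate(rec: SimRecording) -> SimRecording:
    """Re-run the generator with the stored config (determinism helper)."""
    return simulate_recording(replace(rec.config))
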