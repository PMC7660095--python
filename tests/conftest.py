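import numpy as np
import pytest

from writhekit.pose_io import BODY25, N_LANDMARKS, KeypointSequence
from writhekit.synthetic import Regime, SimConfig, simulate_recording


def make_sequence(
    n_frames: int = 10,
    fps: float = 10.0,
    recording_id: str = "rec",
    overrides: dict | None = None,
    conf: float | np.ndarray = 1.0,
) -> KeypointSequence:
    """A simple valid sequence: a spread-out static skeleton.

    ``overrides`` maps landmark name → (n_frames, 2) array or (x, y) tuple.
    """
    xy = np.zeros((n_frames, N_LANDMARKS, 2))
    for j in range(N_LANDMARKS):
        xy[:, j] = (10.0 * j, 5.0 * j + 100.0)
    xy[:, BODY25["neck"]] = (50.0, 20.0)
    xy[:, BODY25["mid_hip"]] = (50.0, 80.0)
    if overrides:
        for name, val in overrides.items():
            xy[:, BODY25[name]] = np.asarray(val, dtype=float)
    c = np.full((n_frames, N_LANDMARKS), 1.0) * conf
    return KeypointSequence(recording_id, fps, xy, np.asarray(c, dtype=float))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def wm_recording():
    """One simulated recording with a wm and an om regime (reduced size)."""
    cfg = SimConfig(
        seed=11,
        recording_id="mix",
        fps=30.0,
        duration_s=60.0,
        regimes=(Regime("wm", 0.0, 30.0), Regime("om", 30.0, 60.0)),
    )
    return simulate_recording(cfg)
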