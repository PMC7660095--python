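import numpy as np
import pytest

from writhekit.features import (
    FEATURE_COLUMNS,
    WindowSpec,
    downsample,
    extract_windows,
    features_table,
    fit_ellipse,
    limb_features,
    limb_length,
    remove_outliers,
)
from writhekit.pose_io import BODY25
from writhekit.preprocess import preprocess_sequence

from conftest import make_sequence

# ---------------------------------------------------------------------------
# independent brute-force references
# ---------------------------------------------------------------------------

def quartile_filter_reference(points):
    """Literal restatement of the IQR rule with interpolated quartiles."""
    points = np.asarray(points, float)
    if len(points) < 8:
        return points
    centroid = points.mean(axis=0)
    d = np.sqrt(((points - centroid) ** 2).sum(axis=1))
    s = np.sort(d)

    def quantile(q):
        pos = q * (len(s) - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        return s[lo] + (pos - lo) * (s[hi] - s[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    cutoff = q3 + 1.5 * (q3 - q1)
    return points[[i for i in range(len(points)) if d[i] <= cutoff]]


def thinning_reference(points, eps):
    """Literal restatement of the greedy radius-thinning rule."""
    points = np.asarray(points, float)
    if eps == 0 or len(points) == 0:
        return points
    kept = [points[0]]
    for p in points[1:]:
        if np.linalg.norm(p - kept[-1]) >= eps:
            kept.append(p)
    return np.array(kept)


class TestRemoveOutliers:
    def test_single_distant_point_removed(self):
        # 12 unit vectors summing to (-10, 0) plus one point at (10, 0):
        # centroid is the origin, distances are twelve 1s and one 10,
        # Q3 = 1, IQR = 0, cutoff = 1 -> only the far point goes
        ct = -10.0 / 12.0
        st = np.sqrt(1 - ct * ct)
        ring = np.array([[ct, st if i % 2 == 0 else -st] for i in range(12)])
        pts = np.vstack([ring, [10.0, 0.0]])
        np.testing.assert_allclose(pts.mean(axis=0), [0, 0], atol=1e-12)
        out = remove_outliers(pts)
        assert len(out) == 12
        assert not any(np.allclose(p, [10, 0]) for p in out)

    def test_identical_points_untouched(self):
        pts = np.ones((20, 2))
        assert len(remove_outliers(pts)) == 20

    def test_below_floor_returned_unchanged(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [500, 500]], float)
        np.testing.assert_array_equal(remove_outliers(pts), pts)

    def test_matches_reference_on_random_clouds(self, rng):
        for _ in range(300):
            n = rng.integers(3, 40)
            pts = rng.normal(0, 1, (n, 2))
            if rng.random() < 0.5:  # sprinkle outliers
                pts[rng.integers(0, n)] *= 20
            np.testing.assert_array_equal(
                remove_outliers(pts), quartile_filter_reference(pts)
            )


class TestDownsample:
    def test_stationary_run_collapses_to_one_point(self):
        pts = np.zeros((100, 2))
        assert len(downsample(pts, 0.5)) == 1

    def test_epsilon_zero_is_identity(self, rng):
        pts = rng.normal(size=(30, 2))
        np.testing.assert_array_equal(downsample(pts, 0.0), pts)

    def test_collinear_unit_spacing_keeps_every_second(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10)])
        out = downsample(pts, 2.0)
        np.testing.assert_array_equal(out[:, 0], [0, 2, 4, 6, 8])

    def test_matches_reference_on_random_walks(self, rng):
        for _ in range(300):
            n = rng.integers(1, 60)
            pts = np.cumsum(rng.normal(0, 1, (n, 2)), axis=0)
            eps = rng.uniform(0, 3)
            np.testing.assert_array_equal(
                downsample(pts, eps), thinning_reference(pts, eps)
            )


class TestFitEllipse:
    def test_recovers_axis_aligned_ellipse(self):
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        pts = np.column_stack([2 * np.cos(theta), np.sin(theta)])
        fit = fit_ellipse(pts)
        assert fit.semi_major == pytest.approx(2.0, rel=1e-9)
        assert fit.semi_minor == pytest.approx(1.0, rel=1e-9)
        assert abs(fit.orientation) < 1e-9

    def test_rotated_ellipse_orientation(self):
        theta = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        raw = np.column_stack([3 * np.cos(theta), 1 * np.sin(theta)])
        ang = 0.6
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        fit = fit_ellipse(raw @ R.T + [5, 7])
        assert fit.center == pytest.approx((5, 7), abs=1e-9)
        assert fit.orientation == pytest.approx(ang, abs=1e-9)

    def test_single_point_degenerates_to_zero_axes(self):
        fit = fit_ellipse(np.tile([[3.0, 4.0]], (5, 1)))
        assert fit.semi_major == 0 and fit.semi_minor == 0
        assert fit.center == (3.0, 4.0)

    def test_collinear_points_have_zero_minor_axis(self):
        t = np.linspace(0, 1, 20)
        pts = np.column_stack([t, 2 * t])
        fit = fit_ellipse(pts)
        assert fit.semi_minor == pytest.approx(0.0, abs=1e-9)
        assert fit.orientation == pytest.approx(np.arctan2(2, 1), abs=1e-9)

    def test_empty_trajectory_errors(self):
        with pytest.raises(ValueError):
            fit_ellipse(np.empty((0, 2)))


class TestLimbLength:
    def test_static_bent_arm(self):
        seq = make_sequence(
            overrides={
                "r_shoulder": (0.0, 0.0),
                "r_elbow": (0.0, 3.0),
                "r_wrist": (4.0, 3.0),
            }
        )
        assert limb_length(seq, "r_arm") == pytest.approx(7.0)

    def test_max_over_frames(self):
        seq = make_sequence(n_frames=3)
        seq.xy[:, BODY25["l_hip"]] = (0, 0)
        seq.xy[:, BODY25["l_knee"]] = [(0, 3.0), (0, 3.5), (0, 3.2)]
        seq.xy[:, BODY25["l_ankle"]] = [(0, 6.9), (0, 7.0), (0, 6.5)]
        assert limb_length(seq, "l_leg") == pytest.approx(7.0)

    def test_invalid_joint_gives_nan(self):
        seq = make_sequence()
        seq.invalid[BODY25["r_elbow"]] = True
        assert np.isnan(limb_length(seq, "r_arm"))


class TestLimbFeatures:
    def test_full_circle_at_proximal_joint(self):
        L = 50.0
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        pts = np.column_stack([L * np.cos(theta), L * np.sin(theta)]) + [10, 20]
        lf = limb_features(fit_ellipse(pts), L, (10.0, 20.0), body_axis_x=0.0)
        assert lf.fma == pytest.approx(1.0, rel=1e-9)
        assert lf.fms == pytest.approx(1.0, rel=1e-9)
        assert lf.cma_h == pytest.approx(0.0, abs=1e-9)
        assert lf.cma_v == pytest.approx(0.0, abs=1e-9)

    def test_half_quarter_axes(self):
        L = 8.0
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        pts = np.column_stack([L / 2 * np.cos(theta), L / 4 * np.sin(theta)])
        lf = limb_features(fit_ellipse(pts), L, (0.0, 0.0), body_axis_x=-1.0)
        assert lf.fma == pytest.approx(0.125, rel=1e-9)
        assert lf.fms == pytest.approx(0.5, rel=1e-9)

    def test_stationary_limb_degenerates_to_zero(self):
        pts = np.tile([[5.0, 5.0]], (10, 1))
        lf = limb_features(fit_ellipse(pts), 10.0, (5.0, 5.0), body_axis_x=0.0)
        assert (lf.fma, lf.fms, lf.cma_h, lf.cma_v) == (0, 0, 0, 0)

    def test_cma_signs(self):
        # head-ward (smaller y) center -> positive cma_v; center away from
        # the body axis -> positive cma_h on either side
        fit_r = fit_ellipse(np.tile([[-20.0, -10.0]], (4, 1)))  # right of axis 0
        lf_r = limb_features(fit_r, 10.0, (-10.0, 0.0), body_axis_x=0.0)
        assert lf_r.cma_v == pytest.approx(1.0)
        assert lf_r.cma_h == pytest.approx(1.0)
        fit_l = fit_ellipse(np.tile([[20.0, -10.0]], (4, 1)))  # left of axis 0
        lf_l = limb_features(fit_l, 10.0, (10.0, 0.0), body_axis_x=0.0)
        assert lf_l.cma_h == pytest.approx(1.0)
        # config switch flips the horizontal sense toward the body axis
        lf_flip = limb_features(fit_l, 10.0, (10.0, 0.0), 0.0, distal_positive=False)
        assert lf_flip.cma_h == pytest.approx(-1.0)

    def test_invalid_length_yields_invalid_vector(self):
        fit = fit_ellipse(np.tile([[0.0, 0.0]], (4, 1)))
        assert not limb_features(fit, 0.0, (0.0, 0.0), 0.0).valid
        assert not limb_features(fit, float("nan"), (0.0, 0.0), 0.0).valid


class TestWindows:
    def test_window_count_with_overlap(self):
        spec = WindowSpec(15.0, 10.0)
        wins = spec.frame_windows(n_frames=60 * 20, fps=20.0)
        assert len(wins) == 10
        assert wins[0] == (0, 300)
        assert wins[-1][0] == 45 * 20

    def test_nonoverlapping_windows(self):
        spec = WindowSpec(30.0, 0.0)
        assert len(spec.frame_windows(60 * 10, 10.0)) == 2

    def test_short_recording_yields_empty_list(self, caplog):
        seq = make_sequence(n_frames=100, fps=10.0)  # 10 s
        out = extract_windows(seq, WindowSpec(15.0, 10.0))
        assert out == []

    def test_overlap_must_be_shorter_than_window(self):
        with pytest.raises(ValueError):
            WindowSpec(15.0, 15.0)

    def test_extracted_features_are_finite_and_tabulate(self, wm_recording):
        seq = preprocess_sequence(wm_recording.seq)
        feats = extract_windows(seq, WindowSpec(15.0, 10.0))
        assert len(feats) == 10  # 60 s at 15/10
        valid = [f for f in feats if f.valid]
        assert valid
        for f in valid:
            assert np.all(np.isfinite(f.features))
            fma = f.features[0::4]
            fms = f.features[1::4]
            assert np.all(fma >= 0)
            assert np.all((fms >= 0) & (fms <= 1))
        table = features_table(feats)
        assert list(table.columns[2:-1]) == list(FEATURE_COLUMNS)
        assert len(table) == 10

    def test_invalid_limb_marks_window(self, wm_recording):
        seq = preprocess_sequence(wm_recording.seq)
        seq.invalid[BODY25["r_wrist"]] = True
        feats = extract_windows(seq, WindowSpec(15.0, 10.0))
        assert all(not f.valid for f in feats)


class TestFeatureInvariants:
    def test_fma_bounded_by_major_axis(self, rng):
        for _ in range(50):
            pts = rng.normal(0, rng.uniform(0.5, 5), (rng.integers(10, 80), 2))
            L = rng.uniform(1, 20)
            fit = fit_ellipse(pts)
            lf = limb_features(fit, L, (0.0, 0.0), -100.0)
            assert lf.fma <= (fit.semi_major / L) ** 2 + 1e-12
            assert 0 <= lf.fms <= 1

    def test_scale_invariance_of_direct_features(self, rng):
        pts = rng.normal(0, 2, (60, 2))
        L = 7.0
        prox = (1.0, -2.0)
        lf1 = limb_features(fit_ellipse(pts), L, prox, body_axis_x=-5.0)
        c = 37.5
        lf2 = limb_features(
            fit_ellipse(pts * c), L * c, (prox[0] * c, prox[1] * c), body_axis_x=-5.0 * c
        )
        np.testing.assert_allclose(lf1.as_array(), lf2.as_array(), rtol=1e-9)
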