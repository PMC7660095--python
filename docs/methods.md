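# Methods

## Problem and model

The package detects writhing movements (WM) — the normal, elliptical,
low-to-moderate-amplitude general movements of newborns in the first weeks
of life — in 2-D pose keypoint recordings, and uses the detected WM content
to separate recordings with normal writhing from those showing a poor
repertoire (PR) of monotonous movement. The central modeling assumption is
that the trajectory of a distal limb landmark (wrist or ankle) during
writhing traces an approximately elliptical path, so the ellipse
circumscribed on a short windowed trajectory summarizes the movement's
scope (FMA), character (FMS) and location (CMA) in a way a clinician can
read directly.

All features are expressed in limb-length units and computed in a
body-anchored frame, so they are invariant to camera scale and to the
infant's position and orientation in the image. This invariance is not
incidental — it is what makes values comparable across infants and
recordings, and it is enforced by construction and verified by tests.

## Preprocessing

* **Gap filling.** A detection with confidence below the threshold
  (default 0.3, configurable; pose estimators emit confidences in [0, 1])
  is replaced by the landmark's most recent confident position; a leading
  gap is back-filled from the first confident one. A landmark never
  detected confidently is flagged invalid and every window that needs it is
  excluded rather than imputed.
* **Smoothing.** Savitzky–Golay, window 31 frames (≈0.5 s at 60 fps),
  polynomial order 3, applied per coordinate channel. The window is long
  enough to suppress per-frame detection jitter and short enough to leave
  sub-second limb motion intact; edges use the filter's truncated-window
  polynomial fit so no invented samples enter the data.
* **Anchoring and rotation.** Per frame, all landmarks are translated so
  the neck sits at a fixed reference (its frame-0 position) and rotated
  about it so the neck→mid-hip vector points down the image (+y, head up).
  This is a per-frame rigid motion — inter-landmark distances are preserved
  exactly — and it is idempotent. Applying it per frame (rather than once
  per recording) tolerates slow drift of the body axis over a multi-second
  window.

The stage order is fill → smooth → anchor/rotate: filling must precede
smoothing so the filter never averages undefined coordinates, and rotation
uses the smoothed axis so frame-to-frame angular jitter does not leak into
the features.

## Feature extraction

Within each window (grid anchored at t = 0, stride = length − overlap,
trailing partial window dropped) and for each of the four limbs:

1. **IQR outlier pass** — distances of all trajectory points from their
   centroid; points beyond Q3 + 1.5·IQR (quartiles by linear interpolation)
   are deleted in a single pass. Trajectories shorter than 8 points are
   left untouched (quartiles of fewer points are too unstable to define
   outliers). A tiny relative slack (1e−9) on the cutoff keeps
   constant-distance trajectories, e.g. a perfect circle, from being
   clipped by floating-point noise.
2. **Radius downsampling** — keep the first point, then each point at
   least ε from the last kept one, ε = 0.005·L by default. This thins the
   pile-up of points where the limb rests, which would otherwise dominate
   the covariance.
3. **Ellipse fit** — centroid plus eigendecomposition of the population
   covariance; semi-axes `sqrt(2·λ)`. The √2 scale is chosen so that
   uniform sampling of an ellipse perimeter recovers exactly that ellipse
   (the variance of `a·cosθ` over a revolution is `a²/2`); consequently
   FMA = 1 means the full reachable circle was swept. Degenerate inputs are
   well-defined: a single point has zero axes, collinear points have zero
   minor axis.
4. **Normalization** — limb length L is measured once per recording as the
   maximum over frames of the two-segment arc length (shoulder–elbow +
   elbow–wrist, or hip–knee + knee–ankle); this is the frame where the limb
   lies most nearly parallel to the image plane and is a lower bound when
   the limb is bent throughout. CMA uses the window-mean proximal-joint
   position as its origin (an instantaneous position would inject the
   joint's own jitter into a window-level feature). The horizontal CMA sign
   points away from the body axis on either side; a config switch
   (`horizontal_distal_positive`) flips it for users who prefer the
   toward-axis convention.

## Consensus labels and agreement

Ground truth comes from K experts' WM intervals (half-open, seconds). A
frame is WM at consensus level N when at least N experts' intervals cover
it; these frame sets shrink monotonically in N, trading label recall for
confidence. Windows are labeled WM when their WM frame fraction reaches the
labeling threshold (default 0.5). Expert agreement is quantified frame-wise
per pair — accuracy and F1 with WM positive, pooled over the recordings both
experts saw — and reported as a K×K table (accuracy above the diagonal, F1
below). Pooling over recordings is the default; with identical recording
durations it equals per-recording averaging up to weighting.

## Detection and evaluation

Windows are classified by one of three detectors behind one interface:
RBF-kernel SVM (C = 1, variance-scaled bandwidth), random forest
(100 trees), or LDA. SVM and LDA are preceded by per-feature z-scoring
fitted on training folds only (an RBF kernel on heterogeneous feature
scales is degenerate); the forest is scale-equivariant and takes raw
features. Evaluation is leave-one-recording-out: standardization and
detector are fitted on all windows of the other recordings. Overlapping
window predictions reduce to a per-frame timeline by majority vote; an
exact tie or an uncovered frame yields OM, the conservative choice for a
detector whose positive class is the *normal* movement. Invalid windows
(any invalid limb) are excluded from training and vote OM.

Frame-level metrics (accuracy, sensitivity, specificity, F1; WM positive)
pool the per-recording confusions. Recording-level screening calls a
recording PR when its detected WM percentage is strictly below a threshold;
sweeping the threshold over all observed percentages (with ±∞ sentinels
closing the curve at (0,0) and (1,1)) gives a ROC whose trapezoidal AUC
equals the concordance statistic, ties counting one half.

## Synthetic data

The generator emulates the structure of the clinical data, not infant
biomechanics: a quasi-static trunk with 1 px Gaussian jitter; distal
landmarks tracing parametric ellipses (position = center + R(φ)·(a·cos ωt,
b·sin ωt)) around rest centers near their proximal joints; elbows and knees
placed by two-link inverse kinematics with fixed segment lengths, so the
measured limb length equals the configured one; isotropic Gaussian
trajectory jitter σ = 0.01·L; 2% confidence dropouts with zeroed
coordinates. Movement regimes: `wm` with semi-axes (0.35·L, 0.20·L) and
angular velocity 0.5–1.0 rad/s, `om` (rest/PR-like) with (0.06·L, 0.05·L)
and 0.3–0.8 rad/s; per-interval axes vary ±15%. WM-rich recordings
alternate wm/om intervals of 15–30 s; PR recordings are om throughout.
Five simulated experts mark the true WM intervals with Gaussian boundary
jitter (σ = 0.5 s). The standard study is 15 + 15 recordings of 120 s at
60 fps — the camera rate of the intended acquisition setup, with duration
and cohort size scaled down from clinical practice to keep a full run in
the tens of seconds. Everything derives from one seed.

What passing tests on this data do show: the feature estimators recover
known generating parameters under realistic detection noise; the full
pipeline — preprocessing through LOOCV and ROC — is wired correctly and
separates elliptical from monotonous motion. What they do not show:
performance on real infants, whose movements are not stationary ellipses,
whose pose estimates fail in structured ways (occlusion by bedding,
caregiver hands), and whose WM/PR boundary is far subtler than the
synthetic regimes. Clinical metrics must come from clinical data.

## Numerical choices and edge cases

* Window grids are computed in integer frames (`round(seconds·fps)`), so
  features and labels align exactly and no float-drift window mismatch can
  occur.
* FMS is defined 0 for a degenerate (zero-major-axis) fit; metric ratios
  with zero denominators are reported as NaN (undefined), never as 0.
* ROC ties resolve by strict inequality (pct < threshold → PR).
* Interval lists are canonicalized on construction: sorted, overlapping or
  touching intervals merged.
* Keypoint tables are written with `%.17g` floats and parsed with
  round-trip precision, so read ∘ write is the identity on the data model.
* Seeds: detectors take an explicit seed (default 42); the study generator
  spawns independent child seeds per recording, so recordings are
  independent but jointly reproducible.

## Known limitations

* Features are 2-D; out-of-plane motion compresses ellipses and biases FMA
  downward.
* Limb length is a lower-bound estimate when a limb never extends.
* Trunk and head movement are not featurized.
* The wm/om regime dichotomy of the generator makes window classification
  easier than the clinical WM/OM distinction; reported synthetic metrics
  are upper bounds on what the same pipeline would achieve clinically.
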