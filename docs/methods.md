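# Methods

This note documents the models implemented in `kinegraph`, the defaults
and why they were chosen, what the synthetic data generator does and does
not emulate, and the numerical choices that affect results.

## Estimation problem

The smoother estimates, for each of seven IMUs and each keyframe, a pose in
SE(3), a velocity, an angular velocity, and a 6-DOF sensor bias, together
with four static knee-axis directions on the unit sphere and twelve static
IMU-to-joint-center offset vectors. With `M` keyframes the manifold
dimension is `126·M + 44`. The posterior factors into Gaussian residual
models (IMU preintegration, bias random walk, angular velocity, knee hinge,
joint centers, axis–segment angles, anthropometric lengths, hard length
windows, left/right discrepancy), and the MAP estimate minimizes the summed
squared Mahalanobis residuals.

Modeling assumptions, in decreasing order of importance:

* **Rigid mounting.** Axes and offsets are constant in each IMU frame.
  Soft-tissue motion violates this; it is absorbed by the hinge and
  joint-center covariances, which is why those covariances should be
  calibrated rather than set to instrument noise alone.
* **Knees are pure hinges.** The knee's minor degrees of freedom
  (femoral rollback, screw-home rotation) appear as hinge-residual noise.
* **Hips and ankles are point-rotation joints** shared by the flanking
  IMU offsets.
* **Gaussian, isotropic factor noise.** Isotropy of the joint-center
  covariance is also what makes the total error exactly invariant under
  the heading gauge (a rotation about gravity maps the residual
  isometrically).

### Identifiability

Global position, velocity, and heading are unobservable (no magnetometer,
no position reference); they are anchored with priors on the first lumbar
keyframe: zero position, zero velocity, and a 1-DOF zero-yaw prior on the
Z-Y-X Euler yaw of its orientation, plus weak zero priors on each IMU's
initial bias (σ = 0.1 m/s², 0.05 rad/s). Each knee axis has a sign
ambiguity — `r` and `−r` produce identical hinge residuals — giving four
equivalent minima per leg, resolved after optimization (below). Without
subject motion the static variables are unidentifiable; the test suite
verifies this directly as rank deficiency of the static block's Schur
complement of the Gauss–Newton information matrix on a motionless dataset.
For a pure hinge the knee center is only determined along the
medial/lateral axis by the axis–segment angle priors, so knee-offset
accuracy along that line is limited by how far the subject's true
axis–segment angles sit from the population means — an inherent property
of population-prior self-calibration, visible in the acceptance report's
`joint_offset_error_mm`.

## Defaults

| parameter | default | unit | rationale |
| --- | --- | --- | --- |
| sample rate | 200 | Hz | typical research-grade wearable logging rate |
| decimation | 20 | samples/keyframe | 10-Hz keyframes capture calibration-speed motion |
| gravity | (0, 0, −9.81) | m/s² | navigation frame z-up |
| σ_ω (gyro density) | 0.005 | rad/s/√Hz | consumer-MEMS-scale white noise |
| σ_a (accel density) | 0.05 | m/s²/√Hz | consumer-MEMS-scale white noise |
| bias walks | 1e-4 | (rad/s, m/s²)/√s | slow in-run drift |
| Σ_g, Σ_K, Σ_j | (0.005 rad/s)², (0.05 rad/s)², (0.01 m)² · I | — | placeholders; calibrate for real use (below) |
| window sharpness `a` | 100 | 1/m | penalty reaches ~its asymptote within ~2 cm of the bound |
| window σ | 0.01 | m | makes a 2-cm violation cost ~1 unit of whitened error |
| LM λ | 1e-5 init, ×/÷10 | — | standard damping schedule |
| convergence | abs 1e-6, rel 1e-4, 10000 iters | — | batch-smoothing convention |

The anthropometric tables shipped in `anthropometry.yaml` (femur
0.394 ± 0.030 m in [0.326, 0.480]; tibia 0.411 ± 0.026 m in [0.344, 0.479];
femoral head separation 0.187 ± 0.009 m in [0, 0.409]; axis–segment angles
84°/96° ± 2.4° for right/left femur and 92°/88° ± 1.2° for right/left
tibia; length discrepancies σ = 0.8 cm femur, 0.6 cm tibia) are population
survey values; male and female per-sex distributions are composed as the
mean of means with summed variances — the enclosing spread of the two
distributions, deliberately conservative. When subject anthropometry is
measured directly, tighten `σ_L` instead.

**Covariance calibration.** `synthetic.calibrate_covariances` mirrors the
calibration one performs against a reference measurement system: evaluate
the hinge and joint-center residuals at reference (here: simulated-truth)
states, fit zero-mean Gaussian covariances, isotropize them (trace/3, which
preserves exact heading-gauge invariance), and floor them by the analytic
gyro-noise contribution. Σ_g is set to the known discrete gyro variance
σ_ω²/Δt. Using mis-scaled covariances degrades mainly the knee-axis
estimates (the hinge factors get over- or under-weighted against the raw
gyro samples).

## Solver

Levenberg–Marquardt on the product manifold. Retractions: right
perturbation `R ← R·exp(δθ)` for rotations with additive navigation-frame
translation (pose tangent ordered rotation-first), additive vectors, and a
geodesic retraction on S² in a deterministic two-vector tangent basis built
from the smallest-magnitude axis component. Analytic Jacobians for every
factor are evaluated family-by-family in batched numpy and verified against
numerical differentiation in the test suite. The damping term scales the
diagonal of `JᵀJ` (multiplicative damping), which is robust to the mixed
units of the state. The normal equations are block-banded in time
(bandwidth ≈ 134) bordered by the 44 static columns ordered last; they are
solved by banded Cholesky plus a dense Schur complement on the statics,
with a sparse-LU fallback. One iteration at M = 600 costs well under a
second; a full 60-s trial converges from the trivial initialization in
about ten iterations.

Initialization is deliberately trivial: identity orientations, zero
positions/velocities/biases/angular velocities, and a nominal skeleton
(axes along IMU +x; offsets ±0.2 m along IMU z for thigh/shank, hips at
(±0.09, 0, −0.1) m from the lumbar IMU, ankles 0.1 m above the foot IMUs).
Rotations are cheaply re-orthonormalized (one polar-Newton step) at every
retraction and exactly (SVD) at the end. If the error turns non-finite the
offending whitened residual row is reported. A stalled search (damping
above 1e12 with no acceptable step) terminates as converged-by-absolute-
change, since no further error reduction is achievable.

The axis–segment angle factors connect only static variables, so they are
included once rather than once per keyframe; replicating them per keyframe
would scale the effective prior weight with trajectory length. The
per-keyframe weighting is recoverable with
`build_graph(..., axis_priors_per_keyframe=True)`, which divides the prior
σ by √M.

## Post-processing

Axis-sign disambiguation proceeds in two steps per leg: (1) rotate both
axes into the navigation frame at every keyframe; if their median angle
exceeds 90° the distal axis is flipped; (2) compute the knee flexion
series; if its median exceeds +20°, both axes pointed left and are flipped.
Step 2 presupposes the trial spends enough time in flexion for the median
to be decisively negative under the flexion-negative convention; a trial
that stands at full extension throughout carries no side information, which
is why the dedicated disambiguation tests use deeply flexed trajectories.
An exact-90° median is reported as genuinely ambiguous.

Anatomical frames are built from the estimated axis and proximal offset
difference: rows (x projected orthogonal to z, z×x, z), normalized — the
normalization is required because the estimated axis need not be orthogonal
to the segment. Composition convention: `R^N_seg = R^N_imu · R_lcsᵀ` where
`R_lcs` rows are the anatomical axes in the IMU frame. Knee angles follow
the joint coordinate system: body-fixed e1 = femoral x, e3 = tibial z,
floating e2 = e3×e1; flexion about e1 (negative in flexion, range roughly
[+10°, −150°]), internal/external rotation about e3, ab/adduction =
±(β − 90°) with β the e1–e3 angle, signs mirrored between sides. The
decomposition is validated by exact round trips over a grid including
±150° flexion; near-gimbal configurations (|e1·e3| > 0.999) still return
angles but set a flag.

## Synthetic data

The generator emulates the study conditions end to end: a
pelvis–femur–tibia–foot chain (ball hips and ankles, hinge knees) whose
joint angles are C² polynomial pulses and windowed sinusoids, so angular
velocity and linear acceleration exist in closed form and the emitted truth
is exactly self-consistent (joint-center coherence to machine precision,
knee relative angular velocity exactly on the axis). The default motion
profile — ankle flexion and circles, ≥90° knee swings, hip
flexion/abduction/rotation, torso bend/twist/side-bend, three repetitions
each over 60 s, with a continuous small pelvis sway — excites every degree
of freedom the estimator needs. Skeletons are sampled from the shipped
anthropometric tables (rejection-sampled into the hard windows; axis
angles truncated at 2.5σ); IMU mounting is randomized up to 20° in
orientation and ±2 cm around nominal positions. The knee axis is tilted in
the femur's frontal plane to meet the sampled femoral angle, and the tibia
carries a constant neutral rotation about the anterior axis so the same
physical axis meets the sampled tibial angle.

Measurements follow the standard model: gyro = body rate + bias + white
noise, accel = specific force + bias + white noise, with discrete noise
variance density²/Δt and seeded random-walk biases. Soft-tissue artifact
is modeled as independent zero-mean sinusoids (default 5 mm, 1°, ~1 Hz
with per-axis frequency jitter) displacing each non-sacral IMU's mounting
pose, propagated analytically into all derivatives.

What the generator does **not** emulate — and therefore what passing tests
do not demonstrate about real data: soft tissue that is correlated with
muscle activation and drifts rather than oscillates, imperfect hinge
kinematics of the real knee (screw-home motion), magnetic or temperature
effects on the sensors, sample dropouts and timing jitter, and ground
contact. Accuracy numbers from synthetic trials are accordingly optimistic
relative to human-subject experiments; the acceptance thresholds are set
as mirrors of, not substitutes for, experimental accuracy.

## Numerical choices

* First-order Euler discretization of the IMU kinematics, matching the
  preintegration model. Its error is the dominant floor in zero-noise
  experiments: at 200 Hz it limits end-to-end flexion recovery to a few
  tenths of a degree, which is why the zero-noise pipeline check in the
  test suite simulates at 400 Hz.
* SO(3) log uses a dedicated near-π branch (axis from the symmetric part)
  so no orientation, however extreme, produces NaNs.
* arccos arguments are clamped to [−1, 1] with a logged warning beyond
  1e-9.
* Covariance fits with fewer samples than dimensions get 1e-12 diagonal
  jitter and a warning.
* Serialization writes floats with 17 significant digits and parses with
  round-trip precision, so write → read → write is byte-identical; parsed
  orientations keep their on-disk quaternions so re-serialization of an
  unmodified solution is also byte-identical.

## Problem sizes used in tests and acceptance

Unit and property tests run on 3-s to 30-s trials at 100 Hz with coarse
keyframing (M = 20–30); the end-to-end acceptance test runs the full 60-s
profile at 200 Hz with 10-Hz keyframes (M = 600); the acceptance script
runs a 30-s trial (M = 300) plus an isolated hinge-axis calibration.
These sizes were chosen so the whole suite exercises every code path at
full fidelity while remaining quick to run on one core.

## Known limitations

* Biases are modeled per keyframe but are only weakly observable over
  short trials; their priors do most of the work early on.
* The offsets' medial/lateral components inherit population-prior error
  (see Identifiability).
* No robust (heavy-tailed) noise models: a single corrupted sample window
  can drag the whitened error substantially.
* The LM implementation is batch-only; there is no sliding-window or
  incremental mode.
* Hip and ankle angles are not derived, only the knee's.
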