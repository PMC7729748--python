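# kinegraph

Magnetometer-free, self-calibrating lower-body inertial motion capture by
factor-graph MAP smoothing.

`kinegraph` estimates lower-body skeletal kinematics from seven body-worn
IMUs (lumbar, both thighs, both shanks, both feet) without magnetometers,
without a known sensor-to-segment alignment, and without a dedicated
functional-calibration procedure. It is written for movement scientists and
wearable-sensing engineers who want ISB-convention knee angles out of raw
gyroscope/accelerometer logs, and for estimation researchers who want a
readable, fully tested reference implementation of the underlying smoother.

## The model

All variables are estimated jointly in one batch nonlinear least-squares
problem (a factor graph). Per keyframe `k` and IMU `s` the states are the
pose `X_{s,k} = (R_{s,k}, p_{s,k}) ∈ SE(3)`, velocity `v_{s,k}`, angular
velocity `ω̂_{s,k}`, and the 6-DOF accelerometer/gyroscope bias `b_{s,k}`.
The static skeleton variables are the knee hinge axes `r_2, r_3, r_5, r_6 ∈ S²`
(each knee's axis expressed in its thigh- and shank-IMU frame) and twelve
IMU-to-joint-center offset vectors `s ∈ R³`. The factors are:

* **IMU preintegration** — the gyro/accel samples between consecutive
  keyframes are compounded into a single relative-motion constraint with a
  propagated covariance and first-order bias Jacobians, so states are
  estimated at 10 Hz while measurements arrive at 200 Hz;
* **bias random walk** and a per-keyframe **angular-velocity** factor
  `ω̂ + b_ω − ω̃ ~ N(0, Σ_g)` tying the angular-velocity state to the raw
  gyro sample at the keyframe;
* **knee hinge** — the relative angular velocity across the knee,
  `m_k = R_Aᵀ R_B ω̂_B − ω̂_A`, must be parallel to the static axis:
  `e_k = m_k − (m_k·r) r ~ N(0, Σ_K)`, written once in the thigh frame and
  once (arguments swapped) in the shank frame;
* **joint centers** — for IMUs flanking a hip/knee/ankle, the static
  offsets map to one common point: `X_A s_A − X_B s_B ~ N(0, Σ_j)`;
* **axis–segment angle** — the angle between the knee axis and the
  femur/tibia proximal direction follows a population distribution
  (femur ≈ 84°/96°, tibia ≈ 92°/88°, right/left), which pins the knee
  center along the otherwise unobservable medial/lateral line;
* **anthropometry** — population priors on femur length, tibia length, and
  femoral head separation, smooth hard-window penalties outside plausible
  ranges, and left/right length-discrepancy constraints.

Because there is no magnetometer or position reference, global position,
velocity, and heading are gauge freedoms; they are anchored by priors on
the first lumbar keyframe. The MAP problem is solved by on-manifold
Levenberg–Marquardt with analytic Jacobians and a banded-plus-arrow sparse
normal-equations solver. Knee axes have a structural sign ambiguity (four
equivalent minima per leg) resolved post hoc, after which femur/tibia
anatomical frames are built from the estimated axis and proximal vector and
the knee's flexion/extension, ab/adduction, and internal/external rotation
are reported in the Grood–Suntay joint coordinate system (flexion negative,
axes per ISB: z proximal, y anterior, x to the subject's right).

Because no public dataset exists for this protocol, the package ships a
first-class synthetic-data module: a pelvis–femur–tibia–foot kinematic
chain with analytic velocities and accelerations, a scripted
calibration-motion profile that excites every lower-body degree of freedom,
an IMU noise/bias model, and an oscillatory soft-tissue perturbation of the
IMU mounting poses.

## Worked example

```sh
kinegraph simulate --seed 42 --out-dir demo
kinegraph estimate --imu demo/imu.csv --out-dir demo/solution
kinegraph evaluate --solution-dir demo/solution --truth-dir demo
```

`simulate` writes a 60-s, 200-Hz seven-IMU measurement table (`imu.csv`)
for a randomly sampled skeleton performing the calibration profile, with
5 mm soft-tissue motion and instrument noise, plus ground-truth sidecars.
`estimate` smooths it (keyframes at 10 Hz; about 10 s on one core) and
writes keyframe states, the estimated skeleton, knee angles, and the solver
log. `evaluate` scores the estimate against the simulated truth and prints:

```json
{
 "distance_rmse_cm_left_shank_left_foot": 0.2975963798450402,
 "distance_rmse_cm_left_thigh_left_shank": 0.4389173729862041,
 "distance_rmse_cm_lumbar_left_thigh": 1.8611356970130568,
 "distance_rmse_cm_lumbar_right_thigh": 2.2032662044169435,
 "distance_rmse_cm_right_shank_right_foot": 0.4267617509215338,
 "distance_rmse_cm_right_thigh_right_shank": 0.4489526259496927,
 "left_knee_flexion_peak_deg": 3.307541456285345,
 "left_knee_flexion_rmse_deg": 1.3015130933440353,
 "mean_distance_rmse_cm": 0.9461050051887452,
 "mean_pitch_rmse_deg": 0.40657351190808305,
 "mean_roll_rmse_deg": 0.36401993635909685,
 "right_knee_flexion_peak_deg": 2.152001395600463,
 "right_knee_flexion_rmse_deg": 0.7324280090187765
}
```

Reading the numbers: knee flexion/extension tracks the simulated truth to
0.7–1.3° RMSE, gravity-referenced orientation (pitch/roll) to ~0.4°, and
the separation between adjacent IMUs to better than 1 cm on average — with
the hip-flanking (lumbar–thigh) pairs noticeably worse than the rest, as
expected for the 3-DOF hip under soft-tissue motion. Absolute heading and
position are not scored: they are unobservable without magnetometers or an
external reference, and all reported quantities are invariant to that gauge.

## Layout

| module | contents |
| --- | --- |
| `kinegraph.manifold` | SO(3)/SE(3)/S² primitives: exp/log, retractions, tangent bases |
| `kinegraph.imu` | measurement model, Euler integration, preintegration, IMU residuals |
| `kinegraph.factors` | hinge, joint-center, axis–segment, anthropometric residuals; prior tables |
| `kinegraph.graph` | factor-graph assembly, gauge priors, batched linearization, LM solver |
| `kinegraph.anatomy` | axis disambiguation, anatomical frames, Grood–Suntay angles, metrics |
| `kinegraph.synthetic` | kinematic-chain simulator, motion scripts, noise synthesis, calibration |
| `kinegraph.io` / `kinegraph.cli` | CSV/JSON/YAML formats and the `kinegraph` command |

See `docs/methods.md` for the modeling assumptions, parameter defaults,
numerical choices, and known limitations.
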