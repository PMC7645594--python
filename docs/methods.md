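# Methods

## Estimation model

### State and dynamics

The fusion filter estimates the 9-vector X = [v_b; a_b; g_b]: body-frame
motion velocity (m/s), motion acceleration (m/s²) and the gravity
acceleration vector resolved in the body frame (m/s²).  Continuous-time
dynamics:

* `dv_b/dt = −[ω_b×] v_b + a_b` — the rigid-body transport identity; the
  gyroscope rate ω_b enters as a known input, its noise as process noise.
* `da_b/dt = η a_b + w₁` — first-order Gauss–Markov model.  η < 0 is the
  inverse correlation time; default −10 s⁻¹ (0.1 s correlation, matching
  limb-motion bandwidth of a few Hz).  σ_w1 (default 50) sets the driving
  noise.  Both are exposed in `FilterParams`; performance is insensitive
  to σ_w1 because the acceleration state is effectively observed through
  the accelerometer (below).
* `dg_b/dt = −[ω_b×] g_b` — exact gravity rotation; no model error
  beyond gyroscope noise.

Discretization at Ts = 0.01 s (100 Hz fused rate; the device's 1 kHz
acquisition/decimation stage is not modeled): the gravity block uses the
Rodrigues closed form of `exp(−[ω×]Ts)` (exactly norm-preserving); the
coupled velocity/acceleration block uses the exact block-triangular
exponential

```
exp([[−W, I],[0, ηI]] Ts) = [[e^{−WTs}, M],[0, e^{ηTs} I]],
M = e^{−WTs} (ηI + W)^{−1} (e^{ηTs} e^{WTs} − I),   W = [ω_b×],
```

with a general matrix-exponential fallback for |η| ≈ 0 and an optional
first-order `I + A Ts` mode.  Per-step process noise, evaluated at the
current estimate:

```
Q = diag( σ_g² Ts² [v×][v×]ᵀ,  σ_w1² Ts² I,  σ_g² Ts² [g×][g×]ᵀ ).
```

**Angular-rate averaging.** The transition from sample k−1 to k uses the
trapezoidal mean of the two gyroscope samples.  Using the left endpoint
alone is equivalent to a half-sample attitude lag (≈ |ω| Ts/2, up to 2°
at running rates) and was the dominant error source in early testing;
the trapezoidal form is standard strapdown practice and causal at update
time.

### Measurements

Y = [v_bm; f_bm] with C = [[I,0,0],[0,−I,I]]: the flow-derived velocity
measures v_b directly, and the accelerometer specific force obeys
f_b = g_b − a_b (sign convention: a level, static accelerometer reads
(0, 0, +g)).  R = diag(σ_v1² I, σ_v2² I) with the device accuracies as
defaults (0.16 m/s, 0.021 m/s²), the standard constant-covariance
reading of a white-Gaussian measurement model.  The update uses the
Joseph form and re-symmetrization; gravity renormalization to |g_b| = g
after the update is available but off by default (propagation preserves
the norm; the update perturbs it by far less than 5%).

Initialization assumes the first 0.5 s quasi-static:
X₀ = [mean v_bm; 0; mean f_bm], P₀ block-diagonal (1e-2, 1e-1, 1e-1).

### Attitude

Roll γ = atan2(g_by, g_bz) (four-quadrant, so inverted poses as in
kicking are resolved); pitch θ = −atan2(g_bx, √(g_by² + g_bz²)), which
is algebraically the roll-compensated single-axis arctangent but
well-behaved when g_bz crosses zero, with θ ∈ [−90°, 90°] (gimbal
convention).  Euler convention throughout is intrinsic Z-Y-X
(yaw–pitch–roll); yaw is unobservable without a magnetometer and exists
only inside the simulator.  All external interfaces use degrees;
internals use radians.  g = 9.80665 m/s², configurable.

### Inertial-only comparator

The baseline filter drops the flow measurement: state [a_b; g_b],
transition diag(e^{ηTs} I, Rodrigues(−ω, Ts)), measurement f = −a + g
only.  Velocity is the classical integral of a_b rotated into the
navigation frame with yaw pinned at 0 (unobservable) — deliberately the
drifting path.  Where the description of the reference method is silent
it mirrors the fusion filter's parameters, so the comparison isolates
the velocity measurement.  It is illustrative of drift, not a navigation
solution.

## Flow-sensor model

Speed from King's law `U² = A + B vⁿ` (defaults A = 1 V², B = 2 V²(m/s)^−n,
n = 0.5, configurable — calibration constants of the physical films are
not public); heading from the three-film directional arctangent with
atan2 semantics, ties at ±180° resolved to +180°; the body velocity is
opposite to the sensed surface flow, v_b = −v_f.  Sub-threshold voltages
(U² < A, possible under noise) map to speed 0 with a warning.  The
directional-gain defaults are α₁ = α₂ = 1, β₁ = β₂ = 0.25: a fully
symmetric layout (β = 0) makes the arctangent denominator
−√3(α₂U₂ + α₁U₃) ≤ 0 for non-negative voltages, leaving half the heading
plane unreachable; small positive β restores four-quadrant coverage.
The simulator-side forward model solves the three linear conditions
(mean voltage, numerator ∝ sin ψ, denominator ∝ cos ψ) for (U₁, U₂, U₃),
shrinking the free modulation scale until all voltages are non-negative.
Sensor validity is 0–3 m/s; the sensor front end clips planar speeds
beyond it with a warning.

## Simulator

The simulator replaces the physical device and the optical reference.
All trajectories are smooth closed-form functions of time evaluated with
a small Taylor-jet arithmetic (value plus three exact time derivatives
propagated through every operation), so body-frame velocity,
acceleration, angular rate and gravity are mutually consistent rigid-body
quantities by construction: finite-difference checks of
`a_b = ω×v + dv/dt` and `dg/dt = −[ω×]g` converge at O(Ts²), and
|g_b| = g to machine precision.  Third derivatives are needed because
the coordination map consumes the shank pitch *rate*.

**Gait.**  A two-link planar-dominant pendulum chain: hip point with
small harmonic bob/sway, thigh of 0.42 m, device 0.10 m below the knee
on the shank.  The shank elevation angle is a three-harmonic Fourier
series of the stride phase; the stride cadence (0.75 + 0.07·v_kmh Hz)
and amplitude (4.0·v − 0.09·v² deg) follow the treadmill speed schedule,
which moves between levels with logistic transitions (τ = 1.5 s; the
phase uses the exact softplus integral of the cadence schedule).  Mild
cycle-to-cycle variability enters as slow phase (0.12 rad) and amplitude
(3%) modulation.  Roll and yaw sway are small fractions of the pitch
amplitude so both attitude channels are exercised.  Amplitudes are
deliberately moderate so that device-point speeds stay inside the flow
sensor's 0–3 m/s validity range (peak ≈ 2.6 m/s at 10 km/h); shank
accelerations still reach tens of m/s².

**Coordination truth.**  Thigh pitch = shank pitch + knee angle, with
the knee angle a fixed smooth logistic map of the normalized
instantaneous shank pitch and pitch rate (bounded below at +2°, so no
hyperextension; peak ≈ 50° in swing).  It is deliberately *not* a neural
network, so training the coordination model is a genuine
function-approximation task with known ground truth, and it depends only
on quantities inside the network's feature set, so the map is exactly
representable.  The harmonic *shape* phases of the gait are drawn from
`GaitProfile.subject_seed`, not the session seed: repeated sessions of
one subject share the waveform and differ in jitter and noise, matching
a per-subject training protocol.

**Strenuous bursts.**  Single segment on a 0.15 m lever arm: Euler
angles are random-phase harmonic sums (0.5–1.8 Hz) spanning the
commanded rotation range (default 70°), and a translational burst
component near 8 Hz is scaled by a root solve so the peak |a_b| lands on
the commanded value (default 120 m/s²; boxing/kicking scale).  At 8 Hz a
120 m/s² burst implies ≈ 2.4 m/s peak speeds — inside the sensor range,
consistent with short sharp strikes.  The first 1.2 s are quiescent so
filters can initialize.  A zero burst rate yields a static run.

**Sensor front end.**  Flow channels are the true planar velocities of
each sensor plane plus iid Gaussian noise (σ_v = 0.16 m/s per channel),
optionally routed through the full voltage forward/inverse model;
accelerometer f = g_b − a_b + noise (σ_f = 0.021 m/s²); gyroscope in
deg/s with optional constant bias (default 0) and noise
(σ_g = 0.21 °/s).  Deterministic given the seed.

What the simulator does *not* emulate: ground-reaction impact
transients, soft-tissue artefacts, treadmill-belt airflow, sensor
temperature drift, calibration errors, or out-of-sagittal knee degrees
of freedom.  Passing the simulation-proxy bounds therefore demonstrates
the estimator's correctness and noise robustness under the stated sensor
accuracies, not end-to-end hardware performance.

## Coordination model and training

Features (11, instantaneous, no temporal window): shank roll/pitch
(deg), v_b (m/s), ω_b (rad/s), a_b (m/s²), z-scored with constants
stored in the model.  Architecture: 30 tanh hidden units, linear
2-output (thigh roll, pitch) — the standard regression reading of a
three-layer back-propagation network.  Training is damped iterative
least squares (Levenberg–Marquardt with analytic Jacobian on the full
batch): steps accepted on the training cost with adaptive damping,
early stopping and model selection on a *chronological* 20% validation
split (random splits leak through autocorrelation).  At 100 Hz adjacent
samples are near-duplicates, so the training block is strided down to at
most 8000 samples.  Training is bit-wise reproducible given the seed.
Models are saved as JSON (weights, normalization, feature order,
training metadata).  `optimize_hidden_neurons` sweeps candidate hidden
sizes with a fixed seed and returns the smallest size within 2% of the
minimum validation RMSE.

The knee angle is β = θ_t − θ_s; when the shank pitch is exact, the knee
error equals the thigh pitch error (algebraic identity, tested).

## Metrics

RMSE, signed mean error (ME — the drift indicator; *not* mean absolute
error) and max |error| per channel; angle channels are differenced on
the circle.  Baseline drift: 4th-order Butterworth low-pass at 0.05 Hz
applied forward-backward (zero phase, so no lag corrupts the drift
estimate); drift + residual reconstructs the input exactly.  Shank
deflection peaks: mean of |θ_s| peaks over the last 25 s window, with a
cadence-adaptive minimum peak separation (half the dominant period from
the window's spectrum).  Maximum knee angle: global max or mean of
per-cycle maxima (both offered; the global max is the default).

## Evaluation campaigns and problem sizes

`limbflow.evaluation` packages the three study conditions:

* strenuous: 120 s runs at 120 m/s² peak, 10 seeds (attitude RMSE, |ME|,
  worst channel of seed means);
* long run: 10 min at 10 km/h (6 s ramp-in from standstill so the
  quasi-static initialization is physically meaningful), 5 seeds
  (per-axis velocity RMSE, attitude RMSE, median max error);
* coordination: 0→10 km/h sweeps in 1 km/h steps held 20 s, one training
  and one independent evaluation session per seed, 5 seeds (worst-seed
  knee |ME| and RMSE).

The test suite exercises the same bounds at moderated sizes (shorter
runs, fewer seeds) chosen to keep the default suite fast;
`scripts/acceptance.py` runs the full campaigns.

## Numerical notes and limitations

* The exact transition exponential is used by default; the
  block-triangular closed form is ~10× faster than a general expm per
  step and matches a 30-term Taylor oracle to 1e-10.
* Velocity differentiation outside the filter
  (`motion_accel_from_series`) uses second-order central differences,
  first-order one-sided at the ends.
* The filter's first-order hold on the acceleration over each 10 ms step
  leaves a forward-velocity floor of ≈ Ts²/2 × jerk (0.03–0.08 m/s at
  running intensity) even with noise-free sensors; immaterial against
  the 0.16 m/s sensor noise, but visible in noise-free self-consistency
  checks.
* The static filter fixed point is unique and exactly stationary
  (zero-innovation property); convergence of the
  gravity-vs-acceleration split from a wrong initial guess is slow
  (~10 s) because that mode is observable only through the velocity
  dynamics.
* Sub-threshold and over-range flow readings are clamped, not rejected;
  heavy clipping (sustained speeds > 3 m/s) would bias the velocity
  channel — gait profile defaults avoid it by construction.
* Yaw is not estimated anywhere; all yaw-dependent quantities in the
  baseline's integrated velocity are illustrative only.
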