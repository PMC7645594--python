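# limbflow

Integral-free limb motion capture from combined micro flow sensing and
inertial sensing, with an intra-limb coordination model that reconstructs
thigh motion from a single shank-worn device.

## The problem

Capturing highly dynamic limb motion (running, boxing, kicking) with
body-worn inertial sensors is hard: the accelerometer measures the *sum*
of gravity and motion acceleration, so velocity must be obtained by
integrating an imperfect acceleration estimate and attitude leans on
integrating the gyroscope — both accumulate drift without bound.

`limbflow` implements an alternative estimation stack built around a
tri-axis flow velocity sensor (two orthogonal hot-film anemometer planes
reading the motion-induced surface flow).  With body-frame velocity
**v**_b measured directly, the motion acceleration follows algebraically
from rigid-body kinematics,

```
a_b = ω_b × v_b + dv_b/dt ,
```

and a tailor-made Kalman filter fuses the flow velocity with the
accelerometer and gyroscope to estimate the 9-dimensional state
[**v**_b; **a**_b; **g**_b]:

* **a**_b follows a first-order Gauss–Markov model `da/dt = η a + w₁`;
* **g**_b (gravity resolved in the body frame) evolves exactly as
  `dg/dt = −[ω_b×] g`, discretized with the Rodrigues closed form;
* measurements are the flow velocity and the specific force
  `f_b = g_b − a_b`.

No channel is ever integrated, so estimation errors stay bounded in
time.  Roll and pitch follow from the gravity estimate:
`γ = atan2(g_by, g_bz)`, `θ = −atan((g_bx/g_bz)·cos γ)`.

The package also provides:

* a hot-film sensor model (King's law `U² = A + B vⁿ` plus the
  three-film directional arctangent) with forward and inverse paths;
* a conventional inertial-only Kalman comparator (accelerometer +
  gyroscope, velocity by integration) to reproduce the drift contrast;
* a physics-consistent limb-motion simulator (treadmill gait sweeps and
  strenuous bursts) whose velocity/acceleration/angular-rate/gravity
  channels satisfy the rigid-body identities to discretization
  precision, plus a sensor front end with the device's stated noise
  (flow 0.16 m/s, accelerometer 0.021 m/s², gyroscope 0.21 °/s);
* the intra-limb coordination model: a 3-layer network (30 tanh hidden
  units) mapping 11 instantaneous shank features (attitude, velocity,
  angular rate, acceleration) to thigh roll/pitch, trained by damped
  iterative least squares; the knee angle is `β = θ_t − θ_s`;
* evaluation metrics: RMSE / signed mean error / max error,
  Butterworth baseline-drift extraction (0.05 Hz, zero-phase), shank
  deflection peaks, maximum knee angle.

## Worked example

```python
import numpy as np
from limbflow import (GaitProfile, NoiseSpec, generate_gait, sensorize,
                      run_fusion, error_report)

truth = generate_gait(GaitProfile(speed_kmh=(0, 10), hold_s=6.0),
                      duration_s=120.0, seed=4)
streams = sensorize(truth, NoiseSpec(seed=4))   # stated sensor noise
est = run_fusion(streams)
rep = error_report(est, truth, channels=["gamma", "theta", "vx"])
print({k: round(v, 3) for k, v in rep.rmse.items()})
```

prints

```
{'gamma': 0.055, 'theta': 0.259, 'vx': 0.094}
```

i.e. on a two-minute 10 km/h run with realistic sensor noise the fused
roll and pitch are good to ~0.05–0.26° RMS and forward velocity to
~0.09 m/s — an order of magnitude inside the device's published error
envelope, while the inertial-only comparator on the same streams drifts
to tens of degrees and hundreds of m/s.

The same pipeline is scriptable from a shell:

```sh
limbflow simulate --profile gait --seed 4 --duration 120 \
    --out-truth truth.csv --out-sensors sensors.csv
limbflow fuse --input sensors.csv --output est.csv
limbflow evaluate --est est.csv --ref truth.csv --report report.json
```

## Layout

```
src/limbflow/
  core_types.py        time series container, frames, units, CSV I/O
  flow_sensing.py      hot-film voltage model, planar inversion, tri-axis composition
  rigid_kinematics.py  skew/Rodrigues, motion acceleration, attitude extraction
  fusion_filter.py     the 9-state flow/inertial Kalman filter
  inertial_baseline.py conventional accelerometer+gyroscope comparator
  motion_simulator.py  gait & strenuous trajectory generator + sensor front end
  coordination.py      shank→thigh network, training, knee angle
  metrics.py           error reports, drift extraction, gait indicators
  evaluation.py        end-to-end study campaigns
  cli.py               `limbflow` command-line interface
```
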