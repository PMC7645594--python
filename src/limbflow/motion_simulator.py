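"""Physics-consistent limb-motion simulator and sensor front end.

Stands in for the physical device and the optical reference: generates
limb trajectories (treadmill gait sweeps, strenuous bursts) whose
body-frame velocity, acceleration, angular rate and gravity vector are
mutually consistent rigid-body quantities, then corrupts them with the
device's stated sensor noise.

Trajectories are smooth closed-form functions of time -- harmonic series
with logistic speed transitions and mild cycle-to-cycle modulation --
evaluated with exact first and second time derivatives carried through
every operation (Taylor-jet differentiation, :class:`Jet`).  The
identities ``a_b = omega x v_b + dv_b/dt`` and
``dg_b/dt = -[omega x] g_b`` therefore hold to machine precision in the
continuous-time sense (a finite-difference check converges at O(Ts^2)),
and ``|g_b| = g`` exactly.

The lower limb is a two-link, planar-dominant pendulum chain (thigh from
the hip, shank from the knee) with small out-of-sagittal roll and yaw
sway so both attitude channels are exercised.  The built-in
shank-to-thigh coordination is a fixed smooth logistic map of the
instantaneous shank state -- deliberately *not* a neural network -- so
that training the coordination model is a genuine function-approximation
task with known ground truth.  Profile defaults keep device-point speeds
inside the flow sensor's 0-3 m/s validity range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core_types import GRAVITY, InputError, NoiseSpec, ProfileError, TimeSeries
from .flow_sensing import FlowSensorParams, forward_planar, invert_planar


class Jet:
    """A scalar signal with exact time derivatives up to third order.

    Holds (value, d/dt, d2/dt2, d3/dt3) as numpy arrays and propagates
    them through arithmetic and elementary functions by the chain rule
    (truncated Taylor-jet arithmetic).  The time variable itself is
    ``Jet(t, 1, 0, 0)``.  Third order is carried because the built-in
    coordination map consumes the shank pitch *rate*, whose second
    derivative -- needed for exact device accelerations -- is the pitch's
    third derivative.
    """

    __slots__ = ("f", "d", "dd", "d3")
    __array_priority__ = 100  # win against ndarray in mixed ops

    def __init__(self, f, d=0.0, dd=0.0, d3=0.0):
        self.f = np.asarray(f, float)
        self.d = np.asarray(d, float)
        self.dd = np.asarray(dd, float)
        self.d3 = np.asarray(d3, float)

    @classmethod
    def time(cls, t: np.ndarray) -> "Jet":
        t = np.asarray(t, float)
        z = np.zeros_like(t)
        return cls(t, np.ones_like(t), z, z)

    def rate(self) -> "Jet":
        """The signal's time derivative as a jet (third order dropped)."""
        return Jet(self.d, self.dd, self.d3, np.zeros_like(self.f))

    def __add__(self, o):
        if isinstance(o, Jet):
            return Jet(self.f + o.f, self.d + o.d, self.dd + o.dd,
                       self.d3 + o.d3)
        return Jet(self.f + o, self.d, self.dd, self.d3)

    __radd__ = __add__

    def __neg__(self):
        return Jet(-self.f, -self.d, -self.dd, -self.d3)

    def __sub__(self, o):
        return self + (-o if isinstance(o, Jet) else -np.asarray(o, float))

    def __rsub__(self, o):
        return (-self) + o

    def __mul__(self, o):
        if isinstance(o, Jet):
            return Jet(
                self.f * o.f,
                self.d * o.f + self.f * o.d,
                self.dd * o.f + 2 * self.d * o.d + self.f * o.dd,
                self.d3 * o.f + 3 * self.dd * o.d + 3 * self.d * o.dd
                + self.f * o.d3)
        return Jet(self.f * o, self.d * o, self.dd * o, self.d3 * o)

    __rmul__ = __mul__

    def __truediv__(self, o):
        if isinstance(o, Jet):
            raise TypeError("divide by constants only")
        return self * (1.0 / o)

    def sin(self):
        s, c = np.sin(self.f), np.cos(self.f)
        d1, d2, d3 = self.d, self.dd, self.d3
        return Jet(s, c * d1, c * d2 - s * d1**2,
                   c * d3 - 3 * s * d1 * d2 - c * d1**3)

    def cos(self):
        s, c = np.sin(self.f), np.cos(self.f)
        d1, d2, d3 = self.d, self.dd, self.d3
        return Jet(c, -s * d1, -s * d2 - c * d1**2,
                   -s * d3 - 3 * c * d1 * d2 + s * d1**3)

    def tanh(self):
        h = np.tanh(self.f)
        u = 1.0 - h**2
        d1, d2, d3 = self.d, self.dd, self.d3
        return Jet(h, u * d1, u * d2 - 2 * h * u * d1**2,
                   u * d3 - 6 * h * u * d1 * d2 + 2 * u * (2 * h**2 - u) * d1**3)

    def logistic(self):
        s = np.where(self.f >= 0, 1.0 / (1.0 + np.exp(-np.abs(self.f))),
                     np.exp(-np.abs(self.f)) / (1.0 + np.exp(-np.abs(self.f))))
        w = s * (1.0 - s)
        q = 1.0 - 2.0 * s
        d1, d2, d3 = self.d, self.dd, self.d3
        return Jet(s, w * d1, w * d2 + w * q * d1**2,
                   w * d3 + 3 * w * q * d1 * d2 + w * (q**2 - 2 * w) * d1**3)

    def softplus(self):
        s = np.where(self.f >= 0, 1.0 / (1.0 + np.exp(-np.abs(self.f))),
                     np.exp(-np.abs(self.f)) / (1.0 + np.exp(-np.abs(self.f))))
        w = s * (1.0 - s)
        q = 1.0 - 2.0 * s
        d1, d2, d3 = self.d, self.dd, self.d3
        return Jet(np.logaddexp(0.0, self.f), s * d1, s * d2 + w * d1**2,
                   s * d3 + 3 * w * d1 * d2 + w * q * d1**3)


def _rot_zyx(psi: Jet, th: Jet, ga: Jet):
    """Body-to-nav rotation (intrinsic Z-Y-X Euler) as a 3x3 list of Jet."""
    cz, sz = psi.cos(), psi.sin()
    cy, sy = th.cos(), th.sin()
    cx, sx = ga.cos(), ga.sin()
    return [
        [cz * cy, cz * sy * sx - sz * cx, cz * sy * cx + sz * sx],
        [sz * cy, sz * sy * sx + cz * cx, sz * sy * cx - cz * sx],
        [-sy, cy * sx, cy * cx],
    ]


def _mat_vec_const(T, c):
    """T (3x3 of Jet) times a constant 3-vector -> list of 3 Jet."""
    return [T[i][0] * c[0] + T[i][1] * c[1] + T[i][2] * c[2] for i in range(3)]


def _stackv(rows) -> np.ndarray:
    return np.stack(rows, axis=1)


def _body_kinematics(T, p, g: float):
    """Exact body-frame kinematics of a device with orientation T
    (body-to-nav, 3x3 of Jet) at nav position p (3 of Jet).

    Returns value arrays (v_b, a_b, omega_b, g_b), each (n, 3).
    """
    Tv = np.array([[T[i][j].f for j in range(3)] for i in range(3)])  # (3,3,n)
    Td = np.array([[T[i][j].d for j in range(3)] for i in range(3)])
    v_n = np.stack([p[i].d for i in range(3)])       # (3, n)
    a_n = np.stack([p[i].dd for i in range(3)])
    v_b = np.einsum("jin,jn->in", Tv, v_n)
    a_b = np.einsum("jin,jn->in", Tv, a_n)
    Om = np.einsum("jin,jkn->ikn", Tv, Td)           # T^T dT/dt
    omega = np.stack([Om[2, 1], Om[0, 2], Om[1, 0]])
    g_b = g * Tv[2]                                  # T^T (0,0,g) = g * row z
    return v_b.T, a_b.T, omega.T, g_b.T


@dataclass
class GaitProfile:
    """Treadmill gait sweep: speed schedule and the maps it drives.

    The speed schedule holds each level for ``hold_s`` seconds with
    smooth logistic transitions (time constant ``trans_tau_s``).  Stride
    cadence and shank elevation amplitude are affine/quadratic maps of
    belt speed; the thigh follows the built-in coordination map.
    ``device_offset_m`` is the device position below the knee along the
    shank.
    """

    speed_kmh: tuple[float, ...] = (0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10)
    hold_s: float = 20.0
    trans_tau_s: float = 1.5
    cadence_base_hz: float = 0.75
    cadence_per_kmh: float = 0.07
    amp_deg_per_kmh: float = 4.0
    amp_deg_quad: float = -0.09
    thigh_len_m: float = 0.42
    device_offset_m: float = 0.10
    harmonics: tuple[float, float] = (0.20, 0.05)  # relative 2nd, 3rd
    roll_frac: float = 0.10
    yaw_frac: float = 0.06
    jitter_phase_rad: float = 0.12
    jitter_amp_frac: float = 0.03
    # Waveform shape (harmonic phase offsets) is a property of the subject,
    # not of the session: repeated sessions of one subject share it, while
    # the session seed only drives cycle-to-cycle jitter and sensor noise.
    subject_seed: int = 0

    def cadence_hz(self, speed_kmh: float) -> float:
        return self.cadence_base_hz + self.cadence_per_kmh * speed_kmh

    def amp_rad(self, speed_kmh: float) -> float:
        return math.radians(
            self.amp_deg_per_kmh * speed_kmh + self.amp_deg_quad * speed_kmh**2)


@dataclass
class StrenuousProfile:
    """Burst activity (boxing/kicking-like): high accelerations, large
    attitude excursions, single segment.

    ``burst_peak_accel`` is the target peak |a_b| in m/s^2; the
    translational burst content sits near ``burst_rate_hz`` so peak
    speeds stay near the flow sensor's validity range.
    """

    burst_rate_hz: float = 8.0
    burst_peak_accel: float = 120.0
    rotation_range_deg: float = 70.0
    rot_freq_band_hz: tuple[float, float] = (0.5, 1.8)
    lever_arm_m: float = 0.15
    n_rot_harmonics: int = 4
    n_burst_harmonics: int = 3
    ramp_in_s: float = 1.2

    def __post_init__(self) -> None:
        if self.burst_peak_accel <= 0:
            raise ProfileError("burst_peak_accel must be > 0")


def _schedule(tt: Jet, levels, value_of, t0s, tau) -> Jet:
    """Smooth schedule: value_of(level) with logistic transitions."""
    expr = Jet(np.full_like(tt.f, float(value_of(levels[0]))))
    for lev_prev, lev, t0 in zip(levels[:-1], levels[1:], t0s):
        expr = expr + (value_of(lev) - value_of(lev_prev)) * (
            (tt - t0) * (1.0 / tau)).logistic()
    return expr


def _schedule_integral(tt: Jet, levels, value_of, t0s, tau) -> Jet:
    """Exact time integral of :func:`_schedule` (softplus form)."""
    expr = tt * float(value_of(levels[0]))
    for lev_prev, lev, t0 in zip(levels[:-1], levels[1:], t0s):
        expr = expr + (value_of(lev) - value_of(lev_prev)) * tau * (
            (tt - t0) * (1.0 / tau)).softplus()
    return expr


def _coordination_map(theta_s: Jet):
    """The built-in shank-to-thigh coordination.

    Knee angle (rad): ``beta = beta0 + beta_max * sigmoid(w0 + w1 x1 + w2 x2)``
    with x1, x2 the normalized shank pitch and pitch rate.  Bounded below
    by beta0 > 0, so the gait truth never hyperextends; a pure function
    of the instantaneous shank state, hence exactly representable from
    the coordination network's feature set.
    """
    x1 = theta_s * (1.0 / 0.50)
    x2 = theta_s.rate() * (1.0 / 7.0)  # pitch rate (rad/s)/7
    z = -0.8 - 0.9 * x1 - 0.4 * x2
    beta = math.radians(2.0) + math.radians(52.0) * z.logistic()
    gamma_extra = 0.02 * x2.tanh()
    return beta, gamma_extra


def coordination_truth(theta_s_deg, theta_s_rate_dps):
    """Numeric reference of the built-in coordination map.

    Given shank pitch (deg) and its rate (deg/s), returns the true knee
    angle (deg).  Useful as an oracle when validating trained models.
    """
    th = Jet(np.radians(theta_s_deg), np.radians(theta_s_rate_dps))
    beta, _ = _coordination_map(th)
    return np.degrees(beta.f)


def generate_gait(profile: GaitProfile, duration_s: float, seed: int = 0,
                  rate_hz: float = 100.0, g: float = GRAVITY) -> TimeSeries:
    """Ground-truth gait run: shank device kinematics plus thigh attitude.

    Returns a series with shank channels (gamma, theta, psi in deg;
    wx..wz in rad/s; vx..vz; ax..az; gbx..gbz), thigh attitude
    (t_gamma, t_theta in deg) and the knee angle (beta, deg).
    """
    lowest = profile.cadence_hz(min(profile.speed_kmh))
    if duration_s < 1.0 / max(lowest, 1e-6):
        raise InputError("duration shorter than one stride")
    subject_rng = np.random.default_rng(profile.subject_seed)
    shape = subject_rng.uniform(0, 2 * np.pi, size=6)  # harmonic/limb phases
    session_rng = np.random.default_rng(seed)
    jit = session_rng.uniform(0, 2 * np.pi, size=2)    # jitter phases
    ph = np.concatenate([jit, shape])
    levels = list(profile.speed_kmh)
    t0s = [profile.hold_s * (i + 1) for i in range(len(levels) - 1)]
    tau = profile.trans_tau_s

    t = np.arange(round(duration_s * rate_hz)) / rate_hz
    tt = Jet.time(t)

    phase = 2 * math.pi * _schedule_integral(tt, levels, profile.cadence_hz,
                                             t0s, tau)
    phase = phase + profile.jitter_phase_rad * (
        2 * math.pi * 0.13 * tt + ph[0]).sin()
    A = _schedule(tt, levels, profile.amp_rad, t0s, tau)
    A = A * (1 + profile.jitter_amp_frac * (2 * math.pi * 0.21 * tt + ph[1]).sin())

    c2, c3 = profile.harmonics
    theta_s = A * (phase.sin() + c2 * (2 * phase + ph[2]).sin()
                   + c3 * (3 * phase + ph[3]).sin()) - 0.15 * A
    gamma_s = profile.roll_frac * A * (phase + ph[4]).sin() + 0.03
    psi_s = profile.yaw_frac * A * (phase + ph[5]).sin()

    beta, gamma_extra = _coordination_map(theta_s)
    theta_t = theta_s + beta
    gamma_t = 0.5 * gamma_s + gamma_extra + 0.01
    psi_t = 0.5 * psi_s

    hip = [
        0.020 * A * (2 * phase + ph[6]).sin(),
        0.015 * A * (phase + ph[7]).sin(),
        0.9 + 0.020 * A * (2 * phase + ph[6] + 1.0).sin(),
    ]
    c_down = (0.0, 0.0, -1.0)
    T_t = _rot_zyx(psi_t, theta_t, gamma_t)
    T_s = _rot_zyx(psi_s, theta_s, gamma_s)
    leg_t = _mat_vec_const(T_t, c_down)
    leg_s = _mat_vec_const(T_s, c_down)
    p_dev = [hip[i] + profile.thigh_len_m * leg_t[i]
             + profile.device_offset_m * leg_s[i] for i in range(3)]

    v_b, a_b, omega, g_b = _body_kinematics(T_s, p_dev, g)
    beta_deg = np.degrees(theta_t.f - theta_s.f)
    return TimeSeries(t, {
        "gamma": np.degrees(gamma_s.f), "theta": np.degrees(theta_s.f),
        "psi": np.degrees(psi_s.f),
        "wx": omega[:, 0], "wy": omega[:, 1], "wz": omega[:, 2],
        "vx": v_b[:, 0], "vy": v_b[:, 1], "vz": v_b[:, 2],
        "ax": a_b[:, 0], "ay": a_b[:, 1], "az": a_b[:, 2],
        "gbx": g_b[:, 0], "gby": g_b[:, 1], "gbz": g_b[:, 2],
        "t_gamma": np.degrees(gamma_t.f), "t_theta": np.degrees(theta_t.f),
        "beta": beta_deg,
    })


def generate_strenuous(profile: StrenuousProfile, duration_s: float,
                       seed: int = 0, rate_hz: float = 100.0,
                       g: float = GRAVITY) -> TimeSeries:
    """Ground-truth burst run (single segment, e.g. wrist or shank).

    Random-phase smooth bursts; the translational burst amplitude is
    solved so the peak |a_b| lands on ``burst_peak_accel``.  Attitude
    excursions span roughly ``rotation_range_deg``; the opening
    ``ramp_in_s`` is quiescent so filters can initialize.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(round(duration_s * rate_hz)) / rate_hz
    if profile.burst_rate_hz == 0:
        # no bursts commanded: the segment simply rests
        z = np.zeros_like(t)
        return TimeSeries(t, {
            "gamma": z, "theta": z, "psi": z,
            "wx": z, "wy": z, "wz": z, "vx": z, "vy": z, "vz": z,
            "ax": z, "ay": z, "az": z,
            "gbx": z, "gby": z, "gbz": np.full_like(t, g),
        })
    tt = Jet.time(t)
    ramp = ((tt - profile.ramp_in_s) * (1.0 / 0.3)).logistic()
    half = math.radians(profile.rotation_range_deg) / 2.0

    def rand_series(total_amp, n, band):
        freqs = rng.uniform(*band, size=n)
        phases = rng.uniform(0, 2 * np.pi, size=n)
        weights = rng.uniform(0.5, 1.0, size=n)
        weights = total_amp * weights / weights.sum()
        out = Jet(np.zeros_like(t))
        for w, f, p in zip(weights, freqs, phases):
            out = out + w * (2 * math.pi * f * tt + p).sin()
        return out

    nr = profile.n_rot_harmonics
    band = profile.rot_freq_band_hz
    gamma = ramp * rand_series(half, nr, band)
    theta = ramp * rand_series(min(half, math.radians(55.0)), nr, band)
    psi = ramp * rand_series(half * 0.5, nr, band)

    fb = profile.burst_rate_hz
    d = [ramp * rand_series(1.0, profile.n_burst_harmonics,
                            (0.8 * fb, 1.2 * fb)) for _ in range(3)]

    T_dev = _rot_zyx(psi, theta, gamma)
    c_down = (0.0, 0.0, -1.0)
    leg = _mat_vec_const(T_dev, c_down)
    p0 = [Jet(np.zeros_like(t)) + profile.lever_arm_m * leg[0],
          Jet(np.zeros_like(t)) + profile.lever_arm_m * leg[1],
          1.2 + profile.lever_arm_m * leg[2]]

    v0, a0, omega, g_b = _body_kinematics(T_dev, p0, g)
    Tv = np.array([[T_dev[i][j].f for j in range(3)] for i in range(3)])
    dv = np.einsum("jin,jn->in", Tv, np.stack([x.d for x in d])).T
    da = np.einsum("jin,jn->in", Tv, np.stack([x.dd for x in d])).T

    target = profile.burst_peak_accel

    def peak(s):
        return np.max(np.linalg.norm(a0 + s * da, axis=1)) - target

    if peak(0.0) > 0.1 * target:
        raise ProfileError("rotational motion alone exceeds the target peak "
                           "acceleration; reduce rotation_range_deg")
    s_hi = 1.0
    for _ in range(60):
        if peak(s_hi) > 0:
            break
        s_hi *= 2.0
    else:
        raise ProfileError("target peak acceleration unreachable "
                           "with the given smoothness")
    s = brentq(peak, 0.0, s_hi, xtol=1e-10)

    v = v0 + s * dv
    a = a0 + s * da
    return TimeSeries(t, {
        "gamma": np.degrees(gamma.f), "theta": np.degrees(theta.f),
        "psi": np.degrees(psi.f),
        "wx": omega[:, 0], "wy": omega[:, 1], "wz": omega[:, 2],
        "vx": v[:, 0], "vy": v[:, 1], "vz": v[:, 2],
        "ax": a[:, 0], "ay": a[:, 1], "az": a[:, 2],
        "gbx": g_b[:, 0], "gby": g_b[:, 1], "gbz": g_b[:, 2],
    })


def sensorize(truth: TimeSeries, noise: NoiseSpec,
              flow_params: FlowSensorParams | None = None,
              via_voltages: bool = False) -> TimeSeries:
    """Noisy sensor streams from a ground-truth run.

    Flow channels are the true planar velocities of each sensor plane
    (sensor 1 in (x_b, y_b), sensor 2 in (x_b, z_b)) plus iid Gaussian
    noise; planar speeds beyond the sensor validity limit are clipped
    with a warning.  The accelerometer reads ``f_b = g_b - a_b`` plus
    noise; the gyroscope reads the angular rate (deg/s in the stream)
    plus bias and noise.  Deterministic given (truth, noise.seed).
    """
    fp = flow_params or FlowSensorParams()
    rng = np.random.default_rng(noise.seed)
    truth.require(["vx", "vy", "vz", "ax", "ay", "az",
                   "gbx", "gby", "gbz", "wx", "wy", "wz"])
    v = truth.stack(("vx", "vy", "vz"))

    def clip_planar(a, b):
        speed = np.hypot(a, b)
        over = speed > fp.v_max
        if over.any():
            warnings.warn(
                f"{int(over.sum())} samples exceed the {fp.v_max} m/s flow "
                "range; clipped", stacklevel=2)
            scale = np.where(over, fp.v_max / np.maximum(speed, 1e-12), 1.0)
            return a * scale, b * scale
        return a, b

    v1x, v1y = clip_planar(v[:, 0], v[:, 1])
    v2x, v2z = clip_planar(v[:, 0], v[:, 2])
    if via_voltages:
        v1x, v1y = _voltage_roundtrip(v1x, v1y, fp)
        v2x, v2z = _voltage_roundtrip(v2x, v2z, fp)
    n = len(truth)
    flow = np.column_stack([v1x, v1y, v2x, v2z]) + rng.normal(
        0.0, noise.sigma_v, size=(n, 4))
    f = (truth.stack(("gbx", "gby", "gbz")) - truth.stack(("ax", "ay", "az"))
         + rng.normal(0.0, noise.sigma_f, size=(n, 3)))
    w_deg = (np.degrees(truth.stack(("wx", "wy", "wz"))) + noise.gyro_bias
             + rng.normal(0.0, noise.sigma_g, size=(n, 3)))
    return TimeSeries(truth.t, {
        "v1bx": flow[:, 0], "v1by": flow[:, 1],
        "v2bx": flow[:, 2], "v2bz": flow[:, 3],
        "fx": f[:, 0], "fy": f[:, 1], "fz": f[:, 2],
        "wx": w_deg[:, 0], "wy": w_deg[:, 1], "wz": w_deg[:, 2],
    })


def _voltage_roundtrip(a, b, fp: FlowSensorParams):
    """Route a planar channel pair through the hot-film voltage model."""
    out_a = np.empty_like(a)
    out_b = np.empty_like(b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(a.size):
            reading = forward_planar((a[i], b[i]), fp)
            out_a[i], out_b[i] = invert_planar(reading, fp)
    return out_a, out_b
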