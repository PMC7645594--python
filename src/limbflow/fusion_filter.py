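"""Flow/inertial Kalman fusion for drift-free limb motion estimation.

State (9): ``X = [v_b; a_b; g_b]`` -- body-frame motion velocity, motion
acceleration and gravity vector.  Dynamics couple velocity to acceleration
through the rigid-body identity ``dv_b/dt = -[omega x] v_b + a_b``, model
the motion acceleration as a first-order Gauss-Markov process
``da_b/dt = eta a_b + w1``, and rotate gravity exactly with the gyroscope
(``dg_b/dt = -[omega x] g_b``).  Measurements (6) are the flow-derived
velocity and the accelerometer specific force ``f_b = g_b - a_b``; neither
channel is integrated, so estimation errors stay bounded in time.

Per-step transition::

    Phi = [[ exp(-[w x] Ts),  M,            0            ],
           [ 0,               e^{eta Ts} I, 0            ],
           [ 0,               0,            exp(-[w x] Ts)]]

with the exact coupling block
``M = exp(-[w x] Ts) (eta I + [w x])^{-1} (e^{eta Ts} exp([w x] Ts) - I)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .core_types import (
    GRAVITY,
    InputError,
    NumericalError,
    TimeSeries,
)
from .flow_sensing import compose_triaxis
from .rigid_kinematics import attitude_series_from_gravity, rodrigues, skew

_I3 = np.eye(3)


@dataclass
class FilterParams:
    """Tuning constants of the fusion filter.

    eta : 1/s
        Gauss-Markov constant of the acceleration model (< 0 for a stable
        process; -10 gives a 0.1 s correlation time, matching limb-motion
        bandwidth of a few Hz).
    sigma_w1 : m/s^3-scale
        Driving-noise standard deviation of the GM acceleration model.
    sigma_g : rad/s
        Gyroscope noise (enters the process noise of the velocity and
        gravity blocks).
    sigma_v1 : m/s, sigma_v2 : m/s^2
        Measurement noise of the flow velocity and the accelerometer.
    """

    eta: float = -10.0
    sigma_w1: float = 50.0
    sigma_g: float = math.radians(0.21)
    sigma_v1: float = 0.16
    sigma_v2: float = 0.021
    ts: float = 0.01
    p0: tuple[float, float, float] = (1e-2, 1e-1, 1e-1)  # per state block
    renormalize_gravity: bool = False
    first_order_phi: bool = False  # I + A1*Ts shortcut for the upper block
    g: float = GRAVITY

    def __post_init__(self) -> None:
        if self.eta >= 0:
            raise ValueError("eta must be < 0 (stable GM process)")
        if self.ts <= 0:
            raise ValueError("Ts must be > 0")
        if min(self.sigma_w1, self.sigma_g, self.sigma_v1, self.sigma_v2) <= 0:
            raise ValueError("all noise standard deviations must be > 0")


@dataclass
class FusionState:
    """Filter state: 9-vector [v_b; a_b; g_b] and 9x9 covariance."""

    X: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float).reshape(9)
        self.P = np.asarray(self.P, dtype=float).reshape(9, 9)


@dataclass
class MeasurementVector:
    """Flow-derived velocity (m/s) and accelerometer specific force (m/s^2)."""

    v_bm: np.ndarray
    f_bm: np.ndarray

    def as_array(self) -> np.ndarray:
        y = np.concatenate([np.asarray(self.v_bm, float).reshape(3),
                            np.asarray(self.f_bm, float).reshape(3)])
        if not np.all(np.isfinite(y)):
            raise ValueError("measurement vector must be finite")
        return y


def _upper_phi(omega_b, p: FilterParams) -> tuple[np.ndarray, np.ndarray, float]:
    """(rotation block, coupling block M, scalar e^{eta Ts})."""
    W = skew(omega_b)
    R = rodrigues(-np.asarray(omega_b, float), p.ts)
    e_eta = math.exp(p.eta * p.ts)
    A = p.eta * _I3 + W
    if abs(p.eta) > 1e-8:
        Rp = rodrigues(np.asarray(omega_b, float), p.ts)
        M = R @ np.linalg.solve(A, e_eta * Rp - _I3)
    else:  # fall back to a general exponential near the singular eta
        A1 = np.block([[-W, _I3], [np.zeros((3, 3)), p.eta * _I3]])
        E = expm(A1 * p.ts)
        M = E[:3, 3:]
    return R, M, e_eta


def build_phi(omega_b, p: FilterParams) -> np.ndarray:
    """9x9 state transition matrix for one sampling period."""
    Phi = np.zeros((9, 9))
    if p.first_order_phi:
        W = skew(omega_b)
        Phi[:3, :3] = _I3 - W * p.ts
        Phi[:3, 3:6] = _I3 * p.ts
        Phi[3:6, 3:6] = _I3 * (1.0 + p.eta * p.ts)
    else:
        R, M, e_eta = _upper_phi(omega_b, p)
        Phi[:3, :3] = R
        Phi[:3, 3:6] = M
        Phi[3:6, 3:6] = e_eta * _I3
    Phi[6:, 6:] = rodrigues(-np.asarray(omega_b, float), p.ts)
    return Phi


def build_Q(v_b, g_b, p: FilterParams) -> np.ndarray:
    """Process-noise covariance evaluated at the current state estimate.

    Velocity block: gyroscope noise leaked through the cross product,
    ``sigma_g^2 Ts^2 [v x][v x]^T``; acceleration block: GM driving noise
    ``sigma_w1^2 Ts^2 I``; gravity block: ``sigma_g^2 Ts^2 [g x][g x]^T``.
    """
    Q = np.zeros((9, 9))
    sv = skew(v_b)
    sg = skew(g_b)
    c = (p.sigma_g * p.ts) ** 2
    Q[:3, :3] = c * (sv @ sv.T)
    Q[3:6, 3:6] = (p.sigma_w1 * p.ts) ** 2 * _I3
    Q[6:, 6:] = c * (sg @ sg.T)
    return Q


def build_measurement_model(p: FilterParams) -> tuple[np.ndarray, np.ndarray]:
    """Constant (C, R): ``Y = [v_b; g_b - a_b] + noise``."""
    C = np.zeros((6, 9))
    C[:3, :3] = _I3
    C[3:, 3:6] = -_I3
    C[3:, 6:] = _I3
    R = np.diag([p.sigma_v1**2] * 3 + [p.sigma_v2**2] * 3)
    return C, R


def kf_step(state: FusionState, omega_b, Y: MeasurementVector,
            p: FilterParams) -> FusionState:
    """One predict/update cycle (Joseph-form covariance update)."""
    C, R = build_measurement_model(p)
    Phi = build_phi(omega_b, p)
    Q = build_Q(state.X[:3], state.X[6:], p)
    x = Phi @ state.X
    P = Phi @ state.P @ Phi.T + Q
    S = C @ P @ C.T + R
    try:
        K = np.linalg.solve(S, C @ P).T
    except np.linalg.LinAlgError as exc:  # pragma: no cover - R > 0 prevents this
        raise NumericalError("singular innovation covariance") from exc
    x = x + K @ (Y.as_array() - C @ x)
    IKC = np.eye(9) - K @ C
    P = IKC @ P @ IKC.T + K @ R @ K.T
    P = 0.5 * (P + P.T)
    if p.renormalize_gravity:
        n = np.linalg.norm(x[6:])
        if n > 0:
            x[6:] *= p.g / n
    return FusionState(x, P)


def initial_state(v_bm: np.ndarray, f_bm: np.ndarray, p: FilterParams,
                  static_s: float = 0.5) -> FusionState:
    """Quasi-static initialization from the opening interval of a run."""
    n = max(1, int(round(static_s / p.ts)))
    x0 = np.concatenate([v_bm[:n].mean(axis=0), np.zeros(3), f_bm[:n].mean(axis=0)])
    P0 = np.diag(np.repeat(p.p0, 3))
    return FusionState(x0, P0)


def run_fusion(streams: TimeSeries, p: FilterParams | None = None) -> TimeSeries:
    """Run the fusion filter over a sensor stream.

    ``streams`` must carry the flow channels (v1bx, v1by, v2bx, v2bz),
    accelerometer (fx, fy, fz) and gyroscope (wx, wy, wz; deg/s).  Returns
    a series with roll/pitch (deg), v_b, a_b, g_b and the gyroscope
    pass-through (rad/s) per sample.
    """
    if len(streams) == 0:
        raise InputError("empty sensor stream")
    if p is None:
        p = FilterParams(ts=streams.ts)
    streams.require(["v1bx", "v1by", "v2bx", "v2bz", "fx", "fy", "fz",
                     "wx", "wy", "wz"])
    v_bm = compose_triaxis(streams["v1bx"], streams["v1by"],
                           streams["v2bx"], streams["v2bz"])
    f_bm = streams.stack(("fx", "fy", "fz"))
    omega = np.radians(streams.stack(("wx", "wy", "wz")))
    # trapezoidal rate for the step k-1 -> k (causal at update time k);
    # the left-endpoint rate alone lags the attitude by half a sample
    omega_step = omega.copy()
    omega_step[1:] = 0.5 * (omega[:-1] + omega[1:])
    n = len(streams)

    C, R = build_measurement_model(p)
    I9 = np.eye(9)
    state = initial_state(v_bm, f_bm, p)
    x, P = state.X, state.P
    out = np.empty((n, 9))
    for k in range(n):
        Phi = build_phi(omega_step[k], p)
        Q = build_Q(x[:3], x[6:], p)
        x = Phi @ x
        P = Phi @ P @ Phi.T + Q
        y = np.concatenate([v_bm[k], f_bm[k]])
        S = C @ P @ C.T + R
        K = np.linalg.solve(S, C @ P).T
        x = x + K @ (y - C @ x)
        IKC = I9 - K @ C
        P = IKC @ P @ IKC.T + K @ R @ K.T
        P = 0.5 * (P + P.T)
        if p.renormalize_gravity:
            nn = np.linalg.norm(x[6:])
            if nn > 0:
                x[6:] *= p.g / nn
        out[k] = x

    gamma, theta = attitude_series_from_gravity(out[:, 6:9])
    ch = {"gamma": gamma, "theta": theta,
          "vx": out[:, 0], "vy": out[:, 1], "vz": out[:, 2],
          "ax": out[:, 3], "ay": out[:, 4], "az": out[:, 5],
          "gbx": out[:, 6], "gby": out[:, 7], "gbz": out[:, 8],
          "wx": omega[:, 0], "wy": omega[:, 1], "wz": omega[:, 2]}
    return TimeSeries(streams.t, ch)
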