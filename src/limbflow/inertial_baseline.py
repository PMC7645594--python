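"""Conventional inertial-only comparator (accelerometer + gyroscope).

A model-based Kalman filter over the 6-state ``[a_b; g_b]``: motion
acceleration follows the same first-order Gauss-Markov model as the fusion
filter, gravity rotates with the gyroscope, and the only measurement is
the accelerometer specific force ``f_b = g_b - a_b``.  Attitude comes from
the estimated gravity vector; velocity is obtained the classical way, by
rotating the estimated motion acceleration to the navigation frame
(yaw fixed at 0, which is unobservable) and integrating -- which is
exactly the path on which errors accumulate.  This comparator exists to
reproduce the drift contrast with the flow-fusion method; it is
illustrative of drift, not a navigation solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core_types import InputError, TimeSeries
from .fusion_filter import FilterParams
from .rigid_kinematics import attitude_series_from_gravity, rodrigues, skew

_I3 = np.eye(3)


@dataclass
class BaselineState:
    """6-state [a_b; g_b] with 6x6 covariance."""

    X: np.ndarray
    P: np.ndarray


def run_inertial_fusion(streams: TimeSeries,
                        p: FilterParams | None = None) -> TimeSeries:
    """Run the inertial-only filter over a sensor stream.

    ``streams`` needs accelerometer (fx, fy, fz) and gyroscope
    (wx, wy, wz; deg/s) channels; flow channels are ignored.  Output
    matches :func:`limbflow.fusion_filter.run_fusion`'s layout, with the
    velocity channels holding the integrated (drifting) estimate.
    """
    if len(streams) == 0:
        raise InputError("empty sensor stream")
    if p is None:
        p = FilterParams(ts=streams.ts)
    streams.require(["fx", "fy", "fz", "wx", "wy", "wz"])
    f_bm = streams.stack(("fx", "fy", "fz"))
    omega = np.radians(streams.stack(("wx", "wy", "wz")))
    omega_step = omega.copy()  # trapezoidal rate, as in the fusion filter
    omega_step[1:] = 0.5 * (omega[:-1] + omega[1:])
    n = len(streams)

    C = np.hstack([-_I3, _I3])  # f = -a + g
    R = p.sigma_v2**2 * _I3
    e_eta = math.exp(p.eta * p.ts)
    qa = (p.sigma_w1 * p.ts) ** 2 * _I3
    c_g = (p.sigma_g * p.ts) ** 2

    n0 = max(1, int(round(0.5 / p.ts)))
    x = np.concatenate([np.zeros(3), f_bm[:n0].mean(axis=0)])
    P = np.diag([p.p0[1]] * 3 + [p.p0[2]] * 3)
    I6 = np.eye(6)
    out = np.empty((n, 6))
    for k in range(n):
        Rg = rodrigues(-omega_step[k], p.ts)
        Phi = np.zeros((6, 6))
        Phi[:3, :3] = e_eta * _I3
        Phi[3:, 3:] = Rg
        sg = skew(x[3:])
        Q = np.zeros((6, 6))
        Q[:3, :3] = qa
        Q[3:, 3:] = c_g * (sg @ sg.T)
        x = Phi @ x
        P = Phi @ P @ Phi.T + Q
        S = C @ P @ C.T + R
        K = np.linalg.solve(S, C @ P).T
        x = x + K @ (f_bm[k] - C @ x)
        IKC = I6 - K @ C
        P = IKC @ P @ IKC.T + K @ R @ K.T
        P = 0.5 * (P + P.T)
        out[k] = x

    gamma, theta = attitude_series_from_gravity(out[:, 3:6])

    # Classical velocity: rotate a_b to nav (yaw = 0) and integrate.
    cg, sg_ = np.cos(np.radians(gamma)), np.sin(np.radians(gamma))
    ct, st = np.cos(np.radians(theta)), np.sin(np.radians(theta))
    a_b = out[:, :3]
    # rows of T_b^n for yaw = 0 (Z-Y-X Euler)
    a_n = np.empty_like(a_b)
    a_n[:, 0] = ct * a_b[:, 0] + st * sg_ * a_b[:, 1] + st * cg * a_b[:, 2]
    a_n[:, 1] = cg * a_b[:, 1] - sg_ * a_b[:, 2]
    a_n[:, 2] = -st * a_b[:, 0] + ct * sg_ * a_b[:, 1] + ct * cg * a_b[:, 2]
    v_n = cumulative_trapezoid(a_n, streams.t, axis=0, initial=0.0)
    # report the velocity back in the body frame (transpose rotation)
    v_b = np.empty_like(v_n)
    v_b[:, 0] = ct * v_n[:, 0] - st * v_n[:, 2]
    v_b[:, 1] = st * sg_ * v_n[:, 0] + cg * v_n[:, 1] + ct * sg_ * v_n[:, 2]
    v_b[:, 2] = st * cg * v_n[:, 0] - sg_ * v_n[:, 1] + ct * cg * v_n[:, 2]

    ch = {"gamma": gamma, "theta": theta,
          "vx": v_b[:, 0], "vy": v_b[:, 1], "vz": v_b[:, 2],
          "ax": out[:, 0], "ay": out[:, 1], "az": out[:, 2],
          "gbx": out[:, 3], "gby": out[:, 4], "gbz": out[:, 5],
          "wx": omega[:, 0], "wy": omega[:, 1], "wz": omega[:, 2]}
    return TimeSeries(streams.t, ch)
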