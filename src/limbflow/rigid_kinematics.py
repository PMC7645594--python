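"""Rigid-body frame kinematics: the integral-free identities.

The central identities, all algebraic in sensed quantities:

* motion acceleration   ``a_b = omega_b x v_b + dv_b/dt``
* gravity propagation   ``dg_b/dt = -[omega_b x] g_b`` with the exact
  per-step solution ``g_b <- exp(-[omega x] Ts) g_b`` (Rodrigues form,
  norm-preserving)
* attitude extraction   roll ``gamma = atan2(g_by, g_bz)``,
  pitch ``theta = -atan((g_bx / g_bz) cos gamma)``

Euler convention is intrinsic yaw-pitch-roll (Z-Y-X); yaw is unobservable
from gravity and is carried only by the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_types import DegenerateGravityError, GRAVITY, InputError, TimeSeries


@dataclass
class Attitude:
    """Roll and pitch in degrees; roll in (-180, 180], pitch in [-90, 90]."""

    gamma: float
    theta: float


def skew(w) -> np.ndarray:
    """Skew-symmetric matrix [w x] such that [w x] u = w x u."""
    wx, wy, wz = np.asarray(w, dtype=float)
    return np.array([[0.0, -wz, wy], [wz, 0.0, -wx], [-wy, wx, 0.0]])


def rodrigues(w, dt: float = 1.0) -> np.ndarray:
    """Rotation matrix exp([w x] dt) in closed form (exactly orthogonal)."""
    w = np.asarray(w, dtype=float) * dt
    phi = float(np.linalg.norm(w))
    W = skew(w)
    if phi < 1e-12:
        # second-order series; error O(phi^3) ~ machine eps here
        return np.eye(3) + W + 0.5 * (W @ W)
    return np.eye(3) + (math.sin(phi) / phi) * W + ((1 - math.cos(phi)) / phi**2) * (W @ W)


def gravity_propagate(g_b, omega_b, ts: float) -> np.ndarray:
    """One-step exact gravity rotation ``exp(-[omega x] Ts) g_b``.

    Norm-preserving by construction; valid whenever ``|omega| Ts < pi``
    (always true at 100 Hz for gyroscope-range rates).
    """
    return rodrigues(-np.asarray(omega_b, float), ts) @ np.asarray(g_b, float)


def motion_accel_from_series(v_b: TimeSeries, omega_b: TimeSeries) -> TimeSeries:
    """Body-frame motion acceleration from velocity and angular-rate series.

    ``a_b[k] = omega_b[k] x v_b[k] + dv_b/dt[k]`` with second-order central
    differences for the derivative (first-order one-sided at the ends).
    Angular rate channels are in rad/s here (internal convention).
    """
    if len(v_b) < 3:
        raise InputError("need at least 3 samples for the velocity derivative")
    v = v_b.stack(("vx", "vy", "vz"))
    w = omega_b.stack(("wx", "wy", "wz"))
    if len(omega_b) != len(v_b):
        raise InputError("velocity and angular-rate series must be aligned")
    vdot = np.gradient(v, v_b.ts, axis=0)
    a = np.cross(w, v) + vdot
    return TimeSeries(v_b.t, {"ax": a[:, 0], "ay": a[:, 1], "az": a[:, 2]})


def attitude_from_gravity(g_b, g: float = GRAVITY) -> Attitude:
    """Roll/pitch (degrees) from the body-frame gravity vector.

    Roll uses four-quadrant atan2(g_by, g_bz) so inverted poses
    (|roll| > 90 deg, as in kicking) are resolved; pitch stays in
    [-90, 90] (gimbal convention).
    """
    g_b = np.asarray(g_b, dtype=float)
    norm = float(np.linalg.norm(g_b))
    if norm <= 0.1 * g:
        raise DegenerateGravityError(
            f"|g_b| = {norm:.3g} m/s^2 too small to define attitude")
    gamma = math.atan2(g_b[1], g_b[2])
    # -atan((g_bx/g_bz) cos gamma) written with hypot(g_by, g_bz) = |g| cos
    # theta in the denominator: identical value, but well-behaved when
    # g_bz passes through zero and clamped to [-90, 90] by construction.
    theta = -math.atan2(g_b[0], math.hypot(g_b[1], g_b[2]))
    return Attitude(math.degrees(gamma), math.degrees(theta))


def attitude_series_from_gravity(gb: np.ndarray, g: float = GRAVITY):
    """Vectorized roll/pitch (degrees) from an (n, 3) gravity array."""
    gamma = np.arctan2(gb[:, 1], gb[:, 2])
    theta = -np.arctan2(gb[:, 0], np.hypot(gb[:, 1], gb[:, 2]))
    return np.degrees(gamma), np.degrees(theta)


def rotation_from_attitude(att: Attitude, yaw_deg: float = 0.0) -> np.ndarray:
    """Body-to-nav rotation T_b^n for intrinsic Z-Y-X Euler angles (degrees).

    Satisfies ``attitude_from_gravity(T_n^b @ (0, 0, g))`` recovering
    (gamma, theta) for any yaw.
    """
    psi, th, ga = (math.radians(yaw_deg), math.radians(att.theta),
                   math.radians(att.gamma))
    cz, sz = math.cos(psi), math.sin(psi)
    cy, sy = math.cos(th), math.sin(th)
    cx, sx = math.cos(ga), math.sin(ga)
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1.0]])
    Ry = np.array([[cy, 0, sy], [0, 1.0, 0], [-sy, 0, cy]])
    Rx = np.array([[1.0, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return Rz @ Ry @ Rx
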