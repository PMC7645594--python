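"""Micro thermal-flow velocity sensor model.

Each planar sensor carries three hot films driven at constant temperature
difference; the feedback voltages (U1, U2, U3) encode flow speed through
King's law and flow direction through a three-film directional arctangent.
Two such sensors mounted in orthogonal planes compose a tri-axis motion
velocity: sensor 1 spans (x_b, y_b), sensor 2 spans (x_b, z_b), and the
shared forward axis is averaged.

The body-frame velocity is opposite to the sensed surface flow
(``v_b = -v_f``): moving the device forward blows air backwards over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_types import ValidityError


@dataclass
class FlowSensorParams:
    """Calibration constants of one planar flow sensor.

    ``alpha`` and ``beta`` are dimensionless directional gains of the
    three-film layout; King's law relates the effective voltage U to flow
    speed via ``U^2 = A + B * v**n``.  The directional-gain defaults are
    chosen so the arctangent covers all four heading quadrants with
    non-negative voltages (a fully symmetric layout with beta = 0 can only
    represent half the heading plane).
    """

    alpha1: float = 1.0
    alpha2: float = 1.0
    beta1: float = 0.25
    beta2: float = 0.25
    kings_A: float = 1.0  # V^2, zero-flow offset
    kings_B: float = 2.0  # V^2 (m/s)^-n
    kings_n: float = 0.5
    v_max: float = 3.0  # m/s, sensor validity limit

    def __post_init__(self) -> None:
        if self.kings_B <= 0:
            raise ValueError("kings_B must be > 0")
        if not 0 < self.kings_n <= 1:
            raise ValueError("kings_n must be in (0, 1]")
        if self.v_max <= 0:
            raise ValueError("v_max must be > 0")

    # Linear forms of the Eq.-26 arctangent in (U1, U2, U3)
    @property
    def _num_coeffs(self) -> np.ndarray:
        a1, a2, b1, b2 = self.alpha1, self.alpha2, self.beta1, self.beta2
        return np.array([a1 * b2 - a2 * b1, a2 + 2 * b2, -(a1 + 2 * b1)])

    @property
    def _den_coeffs(self) -> np.ndarray:
        a1, a2, b1, b2 = self.alpha1, self.alpha2, self.beta1, self.beta2
        return np.sqrt(3.0) * np.array([a1 * b2 + a2 * b1, -a2, -a1])

    @property
    def _mean_coeffs(self) -> np.ndarray:
        return np.array([1.0, 1.0 / self.alpha1, 1.0 / self.alpha2]) / 3.0


@dataclass
class PlanarFlowReading:
    """Hot-film feedback voltages of one planar sensor (volts, >= 0)."""

    U1: float
    U2: float
    U3: float

    def __post_init__(self) -> None:
        if min(self.U1, self.U2, self.U3) < 0:
            raise ValueError("feedback voltages must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.U1, self.U2, self.U3])


def king_voltage_from_speed(speed, p: FlowSensorParams):
    """Forward King's law: effective voltage for a given flow speed."""
    speed = np.asarray(speed, dtype=float)
    return np.sqrt(p.kings_A + p.kings_B * speed**p.kings_n)


def king_speed_from_voltage(U, p: FlowSensorParams):
    """Invert King's law: ``speed = ((U^2 - A)/B)^(1/n)``, clipped at v_max.

    Sub-threshold voltages (``U^2 < A``, possible under noise) map to
    speed 0 with a warning rather than a complex result.
    """
    U = np.asarray(U, dtype=float)
    excess = U**2 - p.kings_A
    if np.any(excess < 0):
        warnings.warn("sub-threshold flow-sensor voltage; speed clamped to 0",
                      stacklevel=2)
    speed = np.where(excess > 0, np.abs(excess) / p.kings_B, 0.0) ** (1.0 / p.kings_n)
    speed = np.where(excess > 0, speed, 0.0)
    return np.minimum(speed, p.v_max)


def invert_planar(reading: PlanarFlowReading, p: FlowSensorParams) -> np.ndarray:
    """Planar body-frame velocity from one sensor's three voltages.

    The effective voltage ``U = (U1 + U2/alpha1 + U3/alpha2)/3`` gives the
    speed through King's law; the heading psi of the surface flow comes
    from the three-film arctangent with four-quadrant (atan2) semantics,
    ties at the +-180 deg branch resolving to +180 deg.  The returned
    velocity uses the body-frame convention ``v_b = -v_f``.
    """
    u = reading.as_array()
    if not u.any():
        warnings.warn("all-zero flow-sensor voltages; returning zero velocity",
                      stacklevel=2)
        return np.zeros(2)
    U = float(p._mean_coeffs @ u)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        speed = float(king_speed_from_voltage(U, p))
    psi = np.arctan2(p._num_coeffs @ u, p._den_coeffs @ u)
    return -speed * np.array([np.cos(psi), np.sin(psi)])


def forward_planar(v_planar, p: FlowSensorParams) -> PlanarFlowReading:
    """Generate voltages that :func:`invert_planar` maps back to ``v_planar``.

    Solves the three linear conditions (mean voltage from King's law, and
    the arctangent numerator/denominator proportional to (sin psi, cos psi))
    for (U1, U2, U3).  The free modulation scale is shrunk as needed to
    keep all voltages non-negative.
    """
    v = np.asarray(v_planar, dtype=float)
    speed = float(np.hypot(v[0], v[1]))
    if speed > p.v_max * (1 + 1e-9):  # tolerate rounding at the boundary
        raise ValidityError(f"|v| = {speed:.3g} m/s exceeds sensor range {p.v_max} m/s")
    Ustar = float(king_voltage_from_speed(speed, p))
    if speed == 0.0:
        # Zero flow: equal baseline voltage on all three films.
        u0 = 3.0 * Ustar / (1.0 + 1.0 / p.alpha1 + 1.0 / p.alpha2)
        return PlanarFlowReading(u0, u0, u0)
    vf = -v  # surface flow opposes device motion
    psi = float(np.arctan2(vf[1], vf[0]))
    M = np.vstack([p._mean_coeffs, p._num_coeffs, p._den_coeffs])
    if abs(np.linalg.det(M)) < 1e-12:
        raise ValidityError("degenerate directional gains: heading not solvable")
    rho = 0.5 * (Ustar**2 - p.kings_A)
    for _ in range(40):
        u = np.linalg.solve(M, np.array([Ustar, rho * np.sin(psi), rho * np.cos(psi)]))
        if np.all(u >= 0):
            return PlanarFlowReading(*u)
        rho *= 0.5
    raise ValidityError(
        "heading not representable with non-negative voltages for these gains")


def compose_triaxis(v1bx, v1by, v2bx, v2bz):
    """Tri-axis body velocity from two orthogonal planar sensors.

    The two sensors share the forward axis x_b, which is averaged;
    sensor 1 supplies y_b and sensor 2 supplies z_b:
    ``v_b = ((v1bx + v2bx)/2, v1by, v2bz)``.
    """
    vx = 0.5 * (np.asarray(v1bx, float) + np.asarray(v2bx, float))
    return np.stack(
        [vx, np.asarray(v1by, float), np.asarray(v2bz, float)], axis=-1
    )
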