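"""Shared containers, frame conventions, units and CSV plumbing.

Conventions used throughout the package:

* Body frame is Forward-Left-Up (FLU): x_b forward, y_b left, z_b up.
* Navigation frame is North-West-Up (NWU): z_n opposite gravity.
* The gravity-acceleration state resolved in the body frame satisfies the
  accelerometer convention ``g_b = f_b + a_b``; when level, the
  accelerometer reads ``(0, 0, g)``.
* Angles are degrees at every external interface (files, public attitude
  types) and radians inside numeric kernels.
* Time series are uniformly sampled; the fused processing rate is 100 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Standard gravity in m/s^2 (configurable per call where it matters).
GRAVITY = 9.80665

#: Default fused processing rate in Hz.
DEFAULT_RATE_HZ = 100.0


class SamplingError(ValueError):
    """Time vector is not uniformly sampled."""


class DataError(ValueError):
    """Required channel missing, misaligned, or contains invalid values."""


class InputError(ValueError):
    """Input series too short or otherwise unusable for an operation."""


class ValidityError(ValueError):
    """Physical quantity outside a sensor's or model's validity range."""


class DegenerateGravityError(ValueError):
    """Gravity-vector estimate too small to define an attitude."""


class NumericalError(RuntimeError):
    """A numerical operation failed (e.g. singular innovation covariance)."""


class MetricError(ValueError):
    """A metric could not be evaluated (e.g. no peaks found)."""


class ProfileError(ValueError):
    """A simulation profile is infeasible as specified."""


_UNIFORM_TOL = 1e-9  # seconds


@dataclass
class TimeSeries:
    """Uniformly sampled multichannel time series.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, monotonically increasing with a uniform
        step (to within 1 ns).
    channels : dict of str -> ndarray
        Named real-valued columns, each the same length as ``t``.
    """

    t: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1:
            raise SamplingError("time vector must be one-dimensional")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            ts = dt[0]
            if ts <= 0 or np.max(np.abs(dt - ts)) >= _UNIFORM_TOL:
                raise SamplingError("time vector is not uniformly increasing")
        self.channels = {
            k: np.asarray(v, dtype=float) for k, v in self.channels.items()
        }
        for name, col in self.channels.items():
            if col.shape != self.t.shape:
                raise DataError(
                    f"channel {name!r} has length {col.size}, expected {self.t.size}"
                )

    def __len__(self) -> int:
        return self.t.size

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise DataError(f"missing channel {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    @property
    def ts(self) -> float:
        """Sampling period in seconds."""
        if self.t.size < 2:
            return math.nan
        return float(self.t[1] - self.t[0])

    @property
    def rate_hz(self) -> float:
        """Sampling frequency in Hz."""
        return 1.0 / self.ts

    def stack(self, names: tuple[str, ...] | list[str]) -> np.ndarray:
        """Return an (n, len(names)) array of the named channels."""
        return np.column_stack([self[n] for n in names])

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t}
        data.update(self.channels)
        return pd.DataFrame(data)

    def require(self, names: list[str] | tuple[str, ...]) -> None:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise DataError(f"missing required channels: {missing}")


@dataclass
class FrameConvention:
    """Names of the body (FLU) and navigation (NWU) frames.

    The gravity field vector in the NWU frame is (0, 0, -g); the
    gravity-acceleration state used by the accelerometer convention
    ``g_b = f_b + a_b`` is (0, 0, +g).
    """

    body: str = "FLU"
    nav: str = "NWU"
    g: float = GRAVITY


@dataclass
class NoiseSpec:
    """Sensor noise levels (device-datasheet accuracies).

    Defaults are the device's stated RMS accuracies: flow velocity
    0.16 m/s, accelerometer 0.021 m/s^2, gyroscope 0.21 deg/s.
    """

    sigma_v: float = 0.16  # m/s, per flow-velocity channel
    sigma_f: float = 0.021  # m/s^2, per accelerometer axis
    sigma_g: float = 0.21  # deg/s, per gyroscope axis
    gyro_bias: float = 0.0  # deg/s, constant per-axis bias
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_v, self.sigma_f, self.sigma_g) < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @property
    def sigma_g_rad(self) -> float:
        return math.radians(self.sigma_g)


#: Channel layout of a sensor CSV file.
SENSOR_CHANNELS = (
    "v1bx", "v1by", "v2bx", "v2bz",  # two planar flow sensors (m/s)
    "fx", "fy", "fz",                # accelerometer specific force (m/s^2)
    "wx", "wy", "wz",                # gyroscope rate (deg/s in files)
)

#: Channel layout of an estimate CSV file.
ESTIMATE_CHANNELS = (
    "gamma", "theta",                # roll, pitch (deg)
    "vx", "vy", "vz",                # body-frame motion velocity (m/s)
    "ax", "ay", "az",                # body-frame motion acceleration (m/s^2)
)


def load_timeseries(path, schema: list[str] | tuple[str, ...] | None = None) -> TimeSeries:
    """Load a CSV time series (first column ``t``, header row mandatory).

    Parameters
    ----------
    path : str or Path
        CSV file, comma-separated, '.' decimal, UTF-8.
    schema : list of str, optional
        Channel names that must be present; NaNs in them are rejected.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    if "t" not in frame.columns:
        raise DataError(f"{path}: first column must be 't'")
    channels = {c: frame[c].to_numpy(float) for c in frame.columns if c != "t"}
    ts = TimeSeries(frame["t"].to_numpy(float), channels)
    if schema is not None:
        ts.require(list(schema))
        for name in schema:
            if np.isnan(ts[name]).any():
                raise DataError(f"channel {name!r} contains NaN")
    return ts


def save_timeseries(ts: TimeSeries, path) -> None:
    """Write a time series to CSV, lossless at double precision."""
    ts.to_frame().to_csv(path, index=False, float_format="%.17g")
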