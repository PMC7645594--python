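"""Evaluation statistics for motion-capture runs.

RMSE / signed mean error / max error per channel, baseline-drift
extraction with a zero-phase Butterworth low-pass, averaged shank
deflection peaks, and maximum knee angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .core_types import DataError, InputError, MetricError, TimeSeries


@dataclass
class ErrorReport:
    """Per-channel error summary against a reference.

    ``me`` is the signed mean error (a drift indicator), not the mean
    absolute error.
    """

    rmse: dict[str, float]
    me: dict[str, float]
    max_abs: dict[str, float]
    n_samples: int


def _wrap_deg(e: np.ndarray) -> np.ndarray:
    return (e + 180.0) % 360.0 - 180.0


def error_report(est: TimeSeries, ref: TimeSeries,
                 channels: list[str] | tuple[str, ...] | None = None,
                 angle_channels: tuple[str, ...] = ("gamma", "theta", "t_gamma",
                                                    "t_theta", "psi"),
                 ) -> ErrorReport:
    """RMSE, signed mean error and max |error| per shared channel.

    Channels named in ``angle_channels`` are differenced on the circle
    (wrapped to (-180, 180]).
    """
    if len(est) != len(ref):
        raise DataError("estimate and reference series have different lengths")
    if channels is None:
        channels = [c for c in est.channels if c in ref.channels]
    rmse, me, mx = {}, {}, {}
    for c in channels:
        e = est[c] - ref[c]
        if c in angle_channels:
            e = _wrap_deg(e)
        rmse[c] = float(np.sqrt(np.mean(e**2)))
        me[c] = float(np.mean(e))
        mx[c] = float(np.max(np.abs(e)))
    return ErrorReport(rmse, me, mx, len(est))


def baseline_drift(series: np.ndarray, rate_hz: float, fc_hz: float = 0.05,
                   order: int = 4):
    """Slow drift component of a series and its residual.

    Zero-phase (forward-backward) Butterworth low-pass at ``fc_hz``;
    returns ``(drift, residual, residual_rmse)`` with
    ``drift + residual == series`` exactly.
    """
    x = np.asarray(series, float)
    if x.size / rate_hz <= 3.0 / fc_hz:
        raise InputError(
            f"series must be longer than {3.0 / fc_hz:.0f} s for a "
            f"{fc_hz} Hz drift estimate")
    b, a = butter(order, fc_hz, btype="low", fs=rate_hz)
    drift = filtfilt(b, a, x)
    residual = x - drift
    return drift, residual, float(np.sqrt(np.mean(residual**2)))


def shank_deflection_peaks(theta_s: np.ndarray, rate_hz: float,
                           window_s: float = 25.0) -> float:
    """Mean peak |shank pitch| (degrees) over the final window.

    Peaks are detected with a minimum separation of half the dominant
    period of the windowed signal (cadence-adaptive).  A fatigue
    indicator: declining values reveal reduced heel lift.
    """
    x = np.abs(np.asarray(theta_s, float))
    nwin = int(round(window_s * rate_hz))
    if nwin > x.size:
        raise InputError("window longer than the series")
    x = x[-nwin:]
    centred = x - x.mean()
    spec = np.abs(np.fft.rfft(centred))
    freqs = np.fft.rfftfreq(x.size, 1.0 / rate_hz)
    if spec[1:].max() <= 1e-9 * max(np.abs(x).max(), 1.0):
        raise MetricError("no oscillation found in the window")
    f_dom = freqs[1:][np.argmax(spec[1:])]
    dist = max(1, int(round(0.5 / f_dom * rate_hz)))
    idx, _ = find_peaks(x, distance=dist,
                        prominence=0.05 * (x.max() - x.min() + 1e-12))
    if idx.size == 0:
        raise MetricError("no peaks found in the window")
    return float(np.mean(x[idx]))


def max_knee_angle(beta: np.ndarray, rate_hz: float | None = None,
                   per_cycle: bool = False) -> float:
    """Maximum knee angle (degrees); optionally the mean of per-cycle maxima.

    Per-cycle mode detects flexion peaks with a cadence-adaptive minimum
    separation (requires ``rate_hz``).
    """
    x = np.asarray(beta, float)
    if x.size == 0:
        raise InputError("empty knee-angle series")
    if not per_cycle:
        return float(np.max(x))
    if rate_hz is None:
        raise InputError("per-cycle mode needs the sampling rate")
    centred = x - x.mean()
    spec = np.abs(np.fft.rfft(centred))
    freqs = np.fft.rfftfreq(x.size, 1.0 / rate_hz)
    if spec[1:].max() <= 1e-9 * max(np.abs(x).max(), 1.0):
        return float(np.max(x))
    f_dom = freqs[1:][np.argmax(spec[1:])]
    dist = max(1, int(round(0.5 / f_dom * rate_hz)))
    idx, _ = find_peaks(x, distance=dist,
                        prominence=0.05 * (x.max() - x.min() + 1e-12))
    if idx.size == 0:
        return float(np.max(x))
    return float(np.mean(x[idx]))
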