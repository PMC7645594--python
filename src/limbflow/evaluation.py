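"""End-to-end evaluation campaigns: the study conditions in code.

Each function regenerates synthetic study data with the device's stated
sensor noise, runs the estimator under test and returns the summary
statistics reported for the corresponding experiment:

* strenuous bursts (peak |a_b| 120 m/s^2)  -> attitude RMSE and signed ME
* long treadmill running at 10 km/h        -> per-axis velocity RMSE,
  attitude RMSE and max |error|
* gait speed sweep + coordination training -> held-out-session knee ME
  and RMSE

Problem sizes are arguments so callers can trade runtime for averaging.
"""

from __future__ import annotations

import warnings

import numpy as np

from .coordination import assemble_features, predict_thigh, train_coordination
from .core_types import NoiseSpec, TimeSeries
from .fusion_filter import FilterParams, run_fusion
from .metrics import error_report
from .motion_simulator import (
    GaitProfile,
    StrenuousProfile,
    generate_gait,
    generate_strenuous,
    sensorize,
)

ATTITUDE = ("gamma", "theta")
VELOCITY = ("vx", "vy", "vz")


def _run(truth: TimeSeries, seed: int):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        streams = sensorize(truth, NoiseSpec(seed=seed))
    return run_fusion(streams, FilterParams(ts=truth.ts))


def strenuous_attitude_errors(duration_s: float = 120.0, n_seeds: int = 10,
                              seed: int = 0) -> dict:
    """Seed-averaged attitude RMSE and |ME| (deg) on strenuous bursts."""
    rmse = {c: [] for c in ATTITUDE}
    me = {c: [] for c in ATTITUDE}
    for k in range(n_seeds):
        s = seed + 1000 * k
        truth = generate_strenuous(StrenuousProfile(), duration_s, seed=s)
        rep = error_report(_run(truth, s), truth, channels=ATTITUDE)
        for c in ATTITUDE:
            rmse[c].append(rep.rmse[c])
            me[c].append(abs(rep.me[c]))
    return {
        "attitude_rmse_deg": max(float(np.mean(rmse[c])) for c in ATTITUDE),
        "attitude_me_deg": max(float(np.mean(me[c])) for c in ATTITUDE),
    }


def long_run_errors(duration_s: float = 600.0, n_seeds: int = 5,
                    seed: int = 0) -> dict:
    """Long 10 km/h treadmill run: velocity and attitude error summary.

    The profile ramps from standstill to 10 km/h over one schedule step so
    the filter's quasi-static initialization is physically meaningful.
    """
    profile = GaitProfile(speed_kmh=(0, 10), hold_s=6.0)
    vel_rmse = {c: [] for c in VELOCITY}
    att_rmse = {c: [] for c in ATTITUDE}
    att_max = {c: [] for c in ATTITUDE}
    for k in range(n_seeds):
        s = seed + 1000 * k
        truth = generate_gait(profile, duration_s, seed=s)
        rep = error_report(_run(truth, s), truth,
                           channels=ATTITUDE + VELOCITY)
        for c in VELOCITY:
            vel_rmse[c].append(rep.rmse[c])
        for c in ATTITUDE:
            att_rmse[c].append(rep.rmse[c])
            att_max[c].append(rep.max_abs[c])
    return {
        "velocity_rmse_ms": max(float(np.mean(vel_rmse[c])) for c in VELOCITY),
        "attitude_rmse_deg": max(float(np.mean(att_rmse[c])) for c in ATTITUDE),
        "attitude_max_deg": max(float(np.median(att_max[c])) for c in ATTITUDE),
    }


def knee_prediction_errors(hold_s: float = 20.0, n_seeds: int = 5,
                           seed: int = 0, n_hidden: int = 30,
                           max_train_samples: int = 8000) -> dict:
    """Coordination-model knee error on held-out sessions.

    For each training seed: generate a training session (0-10 km/h sweep),
    fuse the noisy shank stream, train the network on fused shank features
    with thigh truth targets, then evaluate the knee angle
    ``beta = theta_t_pred - theta_s_est`` against truth on an independent
    session (new session seed, same subject).  Returns the worst seed
    (every seed must meet the bound).
    """
    profile = GaitProfile(hold_s=hold_s)
    duration = (len(profile.speed_kmh) + 1) * hold_s
    mes, rmses = [], []
    for k in range(n_seeds):
        s_train = seed + 1000 * k
        s_eval = seed + 1000 * k + 500
        truth_tr = generate_gait(profile, duration, seed=s_train)
        est_tr = _run(truth_tr, s_train)
        model = train_coordination(
            assemble_features(est_tr),
            truth_tr.stack(("t_gamma", "t_theta")),
            n_hidden=n_hidden, seed=s_train,
            max_train_samples=max_train_samples)
        truth_ev = generate_gait(profile, duration, seed=s_eval)
        est_ev = _run(truth_ev, s_eval)
        pred = predict_thigh(model, assemble_features(est_ev))
        beta_est = pred[:, 1] - est_ev["theta"]
        err = beta_est - truth_ev["beta"]
        mes.append(abs(float(np.mean(err))))
        rmses.append(float(np.sqrt(np.mean(err**2))))
    return {
        "knee_me_deg": max(mes),
        "knee_rmse_deg": max(rmses),
    }
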