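import warnings

import numpy as np
import pytest

from limbflow.core_types import GRAVITY, InputError, NoiseSpec
from limbflow.flow_sensing import FlowSensorParams
from limbflow.motion_simulator import (
    GaitProfile,
    Jet,
    StrenuousProfile,
    generate_gait,
    generate_strenuous,
    sensorize,
)
from .conftest import fd_consistency_residual


class TestJet:
    def test_derivatives_of_composite_expression(self):
        # d/dt and d2/dt2 of sin(t^2) * logistic(t) against closed forms
        t = np.linspace(0.1, 2.0, 50)
        tt = Jet.time(t)
        expr = (tt * tt).sin() * tt.logistic()
        sig = 1 / (1 + np.exp(-t))
        f = np.sin(t**2) * sig
        d1 = 2 * t * np.cos(t**2) * sig + np.sin(t**2) * sig * (1 - sig)
        np.testing.assert_allclose(expr.f, f, atol=1e-12)
        np.testing.assert_allclose(expr.d, d1, atol=1e-12)

        # second and third derivatives against central differences of the
        # lower-order jet components
        def jet_at(x):
            j = Jet.time(np.asarray(x))
            return (j * j).sin() * j.logistic()

        h = 1e-5
        dd_num = (jet_at(t + h).d - jet_at(t - h).d) / (2 * h)
        d3_num = (jet_at(t + h).dd - jet_at(t - h).dd) / (2 * h)
        np.testing.assert_allclose(expr.dd, dd_num, atol=1e-6)
        np.testing.assert_allclose(expr.d3, d3_num, atol=1e-5)


class TestGaitTruth:
    def test_rigid_body_consistency_converges_at_second_order(self):
        prof = GaitProfile(speed_kmh=(0, 8), hold_s=4.0)
        r100 = fd_consistency_residual(generate_gait(prof, 30.0, seed=3))
        r400 = fd_consistency_residual(
            generate_gait(prof, 30.0, seed=3, rate_hz=400.0))
        assert r100 / r400 > 8.0  # ~16 expected for O(Ts^2)
        assert r400 < 0.05

    def test_gravity_identity_and_norm(self, gait_truth):
        gb = gait_truth.stack(("gbx", "gby", "gbz"))
        np.testing.assert_allclose(
            np.linalg.norm(gb, axis=1), GRAVITY, atol=1e-9)

        # dg_b/dt = -[omega x] g_b: finite-difference residual converges
        # at second order in the sampling period
        def resid(rate):
            tr = generate_gait(GaitProfile(hold_s=5.0), 30.0, seed=1,
                               rate_hz=rate)
            g = tr.stack(("gbx", "gby", "gbz"))
            w = tr.stack(("wx", "wy", "wz"))
            gdot = np.gradient(g, tr.ts, axis=0)
            return np.abs(gdot + np.cross(w, g))[2:-2].max()

        r100, r400 = resid(100.0), resid(400.0)
        assert r100 < 1.0
        assert r100 / r400 > 8.0

    def test_zero_speed_is_static(self):
        truth = generate_gait(GaitProfile(speed_kmh=(0.0,)), 10.0, seed=0)
        for ch in ("wx", "wy", "wz", "vx", "vy", "vz", "ax", "ay", "az"):
            assert np.abs(truth[ch]).max() < 1e-12
        assert np.ptp(truth["gbz"]) < 1e-12

    def test_running_acceleration_scale(self):
        truth = generate_gait(GaitProfile(speed_kmh=(0, 10), hold_s=5.0),
                              60.0, seed=5)
        peak = np.linalg.norm(truth.stack(("ax", "ay", "az")), axis=1).max()
        assert 10.0 < peak < 160.0  # tens of m/s^2 at the shank

    def test_device_speed_within_flow_sensor_range(self):
        truth = generate_gait(GaitProfile(), 260.0, seed=6)
        v = truth.stack(("vx", "vy", "vz"))
        assert np.hypot(v[:, 0], v[:, 1]).max() <= 3.0
        assert np.hypot(v[:, 0], v[:, 2]).max() <= 3.0

    def test_knee_angle_physiological_and_periodic(self, gait_truth):
        beta = gait_truth["beta"]
        assert beta.min() >= -5.0
        # dominant frequency of the knee trace in the steady 10 km/h tail
        prof = GaitProfile(hold_s=5.0)
        tail = beta[-1500:] - beta[-1500:].mean()
        freqs = np.fft.rfftfreq(tail.size, gait_truth.ts)
        f_dom = freqs[1:][np.argmax(np.abs(np.fft.rfft(tail))[1:])]
        assert f_dom == pytest.approx(prof.cadence_hz(10.0), rel=0.15)

    def test_duration_shorter_than_stride_rejected(self):
        with pytest.raises(InputError):
            generate_gait(GaitProfile(), 0.5, seed=0)


class TestStrenuousTruth:
    def test_peak_acceleration_hits_target(self, strenuous_truth):
        peak = np.linalg.norm(
            strenuous_truth.stack(("ax", "ay", "az")), axis=1).max()
        assert 108.0 <= peak <= 132.0  # 120 +- 10%

    def test_rigid_body_consistency(self):
        prof = StrenuousProfile()
        r100 = fd_consistency_residual(generate_strenuous(prof, 20.0, seed=7))
        r400 = fd_consistency_residual(
            generate_strenuous(prof, 20.0, seed=7, rate_hz=400.0))
        assert r100 / r400 > 8.0

    def test_zero_burst_rate_is_static(self):
        truth = generate_strenuous(
            StrenuousProfile(burst_rate_hz=0.0), 10.0, seed=0)
        for ch in ("wx", "wy", "wz", "vx", "vy", "vz", "ax", "ay", "az"):
            assert np.abs(truth[ch]).max() == 0.0

    def test_attitude_excursions_within_commanded_range(self, strenuous_truth):
        half = StrenuousProfile().rotation_range_deg / 2
        assert np.abs(strenuous_truth["gamma"]).max() <= half * 1.05
        assert 5.0 < np.abs(strenuous_truth["gamma"]).max()


class TestSensorize:
    def test_zero_noise_reproduces_truth_signals(self, gait_truth):
        quiet = NoiseSpec(sigma_v=0.0, sigma_f=0.0, sigma_g=0.0, seed=0)
        s = sensorize(gait_truth, quiet)
        np.testing.assert_allclose(s["v1by"], gait_truth["vy"], atol=1e-12)
        np.testing.assert_allclose(s["v2bz"], gait_truth["vz"], atol=1e-12)
        np.testing.assert_allclose(
            s["fz"], gait_truth["gbz"] - gait_truth["az"], atol=1e-12)
        np.testing.assert_allclose(
            np.radians(s["wx"]), gait_truth["wx"], atol=1e-12)

    def test_velocity_noise_level_calibrated(self):
        truth = generate_gait(GaitProfile(speed_kmh=(0.0,)), 1000.0, seed=0)
        s = sensorize(truth, NoiseSpec(seed=9))
        resid = s["v1bx"] - truth["vx"]
        assert 0.15 < resid.std() < 0.17

    def test_static_truth_accelerometer_reads_gravity(self):
        truth = generate_gait(GaitProfile(speed_kmh=(0.0,)), 20.0, seed=0)
        s = sensorize(truth, NoiseSpec(seed=2))
        assert s["fz"].mean() == pytest.approx(GRAVITY, abs=0.01)
        assert abs(s["fx"].mean()) < 0.01

    def test_deterministic_given_seed(self, gait_truth):
        a = sensorize(gait_truth, NoiseSpec(seed=42))
        b = sensorize(gait_truth, NoiseSpec(seed=42))
        for ch in a.channels:
            np.testing.assert_array_equal(a[ch], b[ch])

    def test_overspeed_clipped_with_warning(self, strenuous_truth):
        fp = FlowSensorParams(v_max=1.0)
        with pytest.warns(UserWarning, match="clipped"):
            s = sensorize(strenuous_truth,
                          NoiseSpec(sigma_v=0.0, sigma_f=0.0, sigma_g=0.0),
                          flow_params=fp)
        assert np.hypot(s["v1bx"], s["v1by"]).max() <= 1.0 + 1e-9

    def test_voltage_path_round_trip(self):
        truth = generate_gait(GaitProfile(speed_kmh=(0, 4), hold_s=2.0),
                              6.0, seed=3)
        quiet = NoiseSpec(sigma_v=0.0, sigma_f=0.0, sigma_g=0.0, seed=0)
        s = sensorize(truth, quiet, via_voltages=True)
        np.testing.assert_allclose(s["v1by"], truth["vy"], atol=1e-5)
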