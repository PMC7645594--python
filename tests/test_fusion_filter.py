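import math

import numpy as np
import pytest
from scipy.linalg import expm

from limbflow.core_types import GRAVITY, InputError, NoiseSpec, TimeSeries
from limbflow.fusion_filter import (
    FilterParams,
    FusionState,
    MeasurementVector,
    build_measurement_model,
    build_phi,
    build_Q,
    kf_step,
    run_fusion,
)
from limbflow.motion_simulator import GaitProfile, generate_gait, sensorize
from limbflow.rigid_kinematics import skew


def taylor_expm(A, terms=30):
    """Independent brute-force series oracle for the matrix exponential."""
    out = np.eye(A.shape[0])
    term = np.eye(A.shape[0])
    for k in range(1, terms):
        term = term @ A / k
        out = out + term
    return out


def upper_block_A1(omega, eta):
    return np.block([[-skew(omega), np.eye(3)],
                     [np.zeros((3, 3)), eta * np.eye(3)]])


class TestBuildPhi:
    def test_nilpotent_limit(self):
        # omega = 0 and eta -> 0: upper block tends to [[I, Ts I], [0, I]]
        p = FilterParams(eta=-1e-9, ts=0.01)
        Phi = build_phi((0, 0, 0), p)
        np.testing.assert_allclose(Phi[:3, :3], np.eye(3), atol=1e-10)
        np.testing.assert_allclose(Phi[:3, 3:6], 0.01 * np.eye(3), atol=1e-10)
        np.testing.assert_allclose(Phi[3:6, 3:6], np.eye(3), atol=1e-8)

    def test_scalar_exponential_block(self):
        p = FilterParams(eta=-10.0, ts=0.01)
        Phi = build_phi((0, 0, 0), p)
        np.testing.assert_allclose(
            Phi[3:6, 3:6], math.exp(-0.1) * np.eye(3), atol=1e-14)

    def test_matches_taylor_series_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            omega = rng.normal(0, 6, 3)
            eta = -rng.uniform(0.5, 30)
            p = FilterParams(eta=eta, ts=0.01)
            Phi = build_phi(omega, p)
            oracle = taylor_expm(upper_block_A1(omega, eta) * p.ts)
            np.testing.assert_allclose(Phi[:6, :6], oracle, atol=1e-10)
            np.testing.assert_allclose(
                Phi[6:, 6:], taylor_expm(-skew(omega) * p.ts), atol=1e-10)

    def test_first_order_option_close_to_exact(self):
        p_exact = FilterParams(ts=0.01)
        p_fo = FilterParams(ts=0.01, first_order_phi=True)
        omega = np.array([1.0, -2.0, 0.5])
        d = build_phi(omega, p_exact) - build_phi(omega, p_fo)
        assert np.abs(d).max() < 5e-3


class TestBuildQ:
    def test_only_gm_block_when_state_zero(self):
        p = FilterParams(ts=0.01)
        Q = build_Q((0, 0, 0), (0, 0, 0), p)
        expected = np.zeros((9, 9))
        expected[3:6, 3:6] = (p.sigma_w1 * p.ts) ** 2 * np.eye(3)
        np.testing.assert_array_equal(Q, expected)

    def test_skew_outer_product_hand_algebra(self):
        p = FilterParams(ts=0.01)
        Q = build_Q((1, 0, 0), (0, 0, 0), p)
        c = (p.sigma_g * p.ts) ** 2
        np.testing.assert_allclose(Q[:3, :3], c * np.diag([0, 1, 1]), atol=1e-18)

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(5)
        p = FilterParams(ts=0.01)
        for _ in range(50):
            Q = build_Q(rng.normal(0, 3, 3), rng.normal(0, 10, 3), p)
            assert np.linalg.eigvalsh(Q).min() >= -1e-12


class TestMeasurementModel:
    def test_structure_and_rank(self):
        p = FilterParams()
        C, R = build_measurement_model(p)
        x = np.arange(9.0)
        v, a, g = x[:3], x[3:6], x[6:]
        np.testing.assert_array_equal(C @ x, np.concatenate([v, g - a]))
        assert np.linalg.matrix_rank(C) == 6
        np.testing.assert_array_equal(np.diag(R)[:3], p.sigma_v1**2)
        np.testing.assert_array_equal(np.diag(R)[3:], p.sigma_v2**2)
        assert np.all(R == np.diag(np.diag(R)))


class TestKfStep:
    def test_infinite_r_limit_keeps_prior(self):
        p = FilterParams(ts=0.01, sigma_v1=0.16e6, sigma_v2=0.021e6)
        state = FusionState(np.zeros(9), np.diag([1e-2] * 9))
        y = MeasurementVector(np.ones(3), np.ones(3) * 5)
        out = kf_step(state, (0, 0, 0), y, p)
        pred = build_phi((0, 0, 0), p) @ state.X
        np.testing.assert_allclose(out.X, pred, atol=1e-8)

    def test_static_fixed_point(self):
        # the truth is the unique fixed point of the noise-free filter;
        # the slowest mode (gravity/acceleration disambiguation through
        # the velocity dynamics) sets the convergence time scale
        p = FilterParams(ts=0.01)
        g_vec = np.array([0, 0, GRAVITY])
        state = FusionState(np.concatenate([[0.3, -0.2, 0.1], [1, 1, 1],
                                            [1.0, 0.5, 8.0]]), np.eye(9))
        y = MeasurementVector(np.zeros(3), g_vec)
        target = np.concatenate([np.zeros(6), g_vec])
        errs = []
        for k in range(2000):
            state = kf_step(state, (0, 0, 0), y, p)
            if k in (99, 999, 1999):
                errs.append(np.abs(state.X - target).max())
        assert errs[0] < 1e-2 and errs[1] < 1e-4 and errs[2] < 1e-5
        assert errs[0] > errs[1] > errs[2]

    def test_zero_innovation_leaves_state_unchanged(self):
        p = FilterParams(ts=0.01)
        g_vec = np.array([0, 0, GRAVITY])
        x = np.concatenate([np.zeros(6), g_vec])  # exact static state
        state = FusionState(x, np.diag([1e-2] * 9))
        y = MeasurementVector(np.zeros(3), g_vec)
        out = kf_step(state, (0, 0, 0), y, p)
        np.testing.assert_allclose(out.X, x, atol=1e-10)


class TestBatchEquivalence:
    def test_filter_matches_joint_gaussian_conditioning(self):
        """On a matched linear-Gaussian problem the Kalman posterior mean at
        the final step equals conditioning the joint Gaussian of
        (X_N, Y_1..Y_N) on the stacked measurements."""
        rng = np.random.default_rng(6)
        p = FilterParams(ts=0.01)
        omega = np.array([0.8, -0.4, 1.1])  # fixed -> time-invariant system
        Phi = build_phi(omega, p)
        vb, gb = rng.normal(0, 1, 3), rng.normal(0, 4, 3)
        Q = build_Q(vb, gb, p) + 1e-8 * np.eye(9)
        C, R = build_measurement_model(p)
        N = 40
        mu0 = rng.normal(0, 1, 9)
        P0 = np.diag(rng.uniform(0.5, 2.0, 9))

        ys = [rng.normal(0, 1, 6) for _ in range(N)]

        # Kalman recursion with frozen (Phi, Q)
        x, P = mu0.copy(), P0.copy()
        for y in ys:
            x = Phi @ x
            P = Phi @ P @ Phi.T + Q
            S = C @ P @ C.T + R
            K = np.linalg.solve(S, C @ P).T
            x = x + K @ (y - C @ x)
            IKC = np.eye(9) - K @ C
            P = IKC @ P @ IKC.T + K @ R @ K.T

        # independent batch oracle: propagate joint mean/covariance linearly
        means = [mu0]
        covs = {(0, 0): P0}
        for k in range(1, N + 1):
            means.append(Phi @ means[-1])
        # cov(X_j, X_k) built from the recursion X_{k+1} = Phi X_k + w_k
        P_diag = [P0]
        for k in range(N):
            P_diag.append(Phi @ P_diag[-1] @ Phi.T + Q)

        def cov_states(j, k):
            # j <= k: cov(X_j, X_k) = P_j (Phi^{k-j})^T
            M = np.eye(9)
            for _ in range(k - j):
                M = Phi @ M
            return P_diag[j] @ M.T

        mu_y = np.concatenate([C @ means[k] for k in range(1, N + 1)])
        Syy = np.zeros((6 * N, 6 * N))
        Sxy = np.zeros((9, 6 * N))
        for a in range(1, N + 1):
            for b in range(1, N + 1):
                j, k = min(a, b), max(a, b)
                cab = cov_states(j, k)
                block = C @ (cab if a <= b else cab.T) @ C.T
                Syy[(a - 1) * 6:a * 6, (b - 1) * 6:b * 6] = block
            Syy[(a - 1) * 6:a * 6, (a - 1) * 6:a * 6] += R
            Sxy[:, (a - 1) * 6:a * 6] = cov_states(a, N).T @ C.T
        y_stack = np.concatenate(ys)
        x_batch = means[N] + Sxy @ np.linalg.solve(Syy, y_stack - mu_y)

        np.testing.assert_allclose(x, x_batch, atol=1e-6)


class TestRunFusion:
    def test_empty_stream_rejected(self):
        with pytest.raises(InputError):
            run_fusion(TimeSeries([], {c: [] for c in
                                       ("v1bx", "v1by", "v2bx", "v2bz",
                                        "fx", "fy", "fz", "wx", "wy", "wz")}))

    def test_constant_velocity_line_gives_zero_acceleration(self):
        n = 500
        t = np.arange(n) * 0.01
        v = np.array([1.2, 0.0, 0.0])
        streams = TimeSeries(t, {
            "v1bx": np.full(n, v[0]), "v1by": np.zeros(n),
            "v2bx": np.full(n, v[0]), "v2bz": np.zeros(n),
            "fx": np.zeros(n), "fy": np.zeros(n), "fz": np.full(n, GRAVITY),
            "wx": np.zeros(n), "wy": np.zeros(n), "wz": np.zeros(n)})
        est = run_fusion(streams)
        a = est.stack(("ax", "ay", "az"))[100:]
        assert np.abs(a).max() < 1e-6

    def test_noise_free_gait_self_consistency(self):
        # exact sensors on a walking sweep: errors collapse to the
        # first-order-hold discretization floor (velocity ~ Ts^2/2 * jerk
        # on the forward axis), far below the noisy-case error budget
        truth = generate_gait(GaitProfile(speed_kmh=(0, 3, 5), hold_s=5.0),
                              45.0, seed=1)
        tiny = NoiseSpec(sigma_v=1e-12, sigma_f=1e-12, sigma_g=1e-12, seed=0)
        est = run_fusion(sensorize(truth, tiny))
        err_g = est["gamma"] - truth["gamma"]
        err_t = est["theta"] - truth["theta"]
        assert np.sqrt(np.mean(err_g**2)) < 0.2
        assert np.sqrt(np.mean(err_t**2)) < 0.2
        for ch in ("vx", "vy", "vz"):
            e = est[ch] - truth[ch]
            assert np.sqrt(np.mean(e**2)) < 0.05

    def test_gravity_norm_stays_within_5_percent(self, gait_estimate):
        gb = gait_estimate.stack(("gbx", "gby", "gbz"))
        norms = np.linalg.norm(gb[100:], axis=1)
        assert np.all(np.abs(norms - GRAVITY) < 0.05 * GRAVITY)
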