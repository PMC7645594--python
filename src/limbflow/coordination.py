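"""Intra-limb coordination: predicting thigh attitude from shank motion.

A three-layer feed-forward network (tanh hidden layer, linear output)
maps the instantaneous shank motion -- attitude, velocity, angular rate,
acceleration, 11 features in all -- to the thigh attitude angles
(roll, pitch).  Training is damped iterative least squares
(Levenberg-Marquardt on the full batch) with early stopping on a
chronological 20% validation split.  The knee angle follows algebraically
as ``beta = theta_t - theta_s``.

Models are trained per subject/session; inputs are z-scored with
normalization constants stored in the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core_types import DataError, TimeSeries

FEATURE_ORDER = ("gamma", "theta", "vx", "vy", "vz",
                 "wx", "wy", "wz", "ax", "ay", "az")
OUTPUT_ORDER = ("t_gamma", "t_theta")


@dataclass
class CoordinationModel:
    """Weights and input normalization of the shank-to-thigh network."""

    W1: np.ndarray  # (n_hidden, 11)
    b1: np.ndarray  # (n_hidden,)
    W2: np.ndarray  # (2, n_hidden)
    b2: np.ndarray  # (2,)
    input_mean: np.ndarray  # (11,)
    input_std: np.ndarray   # (11,)
    feature_order: tuple[str, ...] = FEATURE_ORDER
    output_order: tuple[str, ...] = OUTPUT_ORDER
    meta: dict = field(default_factory=dict)

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    def to_json(self, path) -> None:
        payload = {
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2.tolist(),
            "input_mean": self.input_mean.tolist(),
            "input_std": self.input_std.tolist(),
            "feature_order": list(self.feature_order),
            "output_order": list(self.output_order),
            "meta": self.meta,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CoordinationModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            np.array(d["W1"]), np.array(d["b1"]),
            np.array(d["W2"]), np.array(d["b2"]),
            np.array(d["input_mean"]), np.array(d["input_std"]),
            tuple(d["feature_order"]), tuple(d["output_order"]), d["meta"])


def assemble_features(shank_estimate: TimeSeries) -> np.ndarray:
    """(n, 11) raw feature matrix in canonical order.

    Angles in degrees, velocity m/s, angular rate rad/s, acceleration
    m/s^2, exactly as produced by the fusion filter's output series.
    """
    shank_estimate.require(FEATURE_ORDER)
    return shank_estimate.stack(FEATURE_ORDER)


def _forward(params, X):
    W1, b1, W2, b2 = params
    H = np.tanh(X @ W1.T + b1)
    return H @ W2.T + b2, H


def _pack(W1, b1, W2, b2):
    return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])


def _unpack(p, n_hidden, n_in, n_out):
    i = 0
    W1 = p[i:i + n_hidden * n_in].reshape(n_hidden, n_in); i += n_hidden * n_in
    b1 = p[i:i + n_hidden]; i += n_hidden
    W2 = p[i:i + n_out * n_hidden].reshape(n_out, n_hidden); i += n_out * n_hidden
    b2 = p[i:i + n_out]
    return W1, b1, W2, b2


def _jacobian(params, X):
    """Analytic Jacobian of the flattened residual wrt packed parameters.

    Residual ordering: sample-major, output-minor.
    """
    W1, b1, W2, b2 = params
    n, n_in = X.shape
    n_hidden, n_out = W1.shape[0], W2.shape[0]
    H = np.tanh(X @ W1.T + b1)          # (n, h)
    dH = 1.0 - H**2                     # (n, h)
    npar = n_hidden * (n_in + 1) + n_out * (n_hidden + 1)
    J = np.zeros((n * n_out, npar))
    # d out_o / d W1[h, i] = W2[o, h] * dH[:, h] * X[:, i]
    G = dH[:, :, None] * X[:, None, :]              # (n, h, in)
    for o in range(n_out):
        block = (W2[o][None, :, None] * G).reshape(n, n_hidden * n_in)
        J[o::n_out, :n_hidden * n_in] = block
        J[o::n_out, n_hidden * n_in:n_hidden * (n_in + 1)] = W2[o] * dH
        J[o::n_out,
          n_hidden * (n_in + 1) + o * n_hidden:
          n_hidden * (n_in + 1) + (o + 1) * n_hidden] = H
        J[o::n_out, n_hidden * (n_in + 1) + n_out * n_hidden + o] = 1.0
    return J


def train_coordination(features: np.ndarray, targets: np.ndarray,
                       n_hidden: int = 30, seed: int = 0,
                       max_iter: int = 80, patience: int = 10,
                       val_frac: float = 0.2,
                       max_train_samples: int = 8000) -> CoordinationModel:
    """Train the coordination network by damped iterative least squares.

    A chronological ``1 - val_frac`` / ``val_frac`` split avoids
    autocorrelation leakage; Levenberg-Marquardt steps on the training
    block are accepted/rejected on the training cost, while early
    stopping and model selection use the validation RMSE.  At 100 Hz
    adjacent samples are near-duplicates, so the training block is
    strided down to at most ``max_train_samples`` samples.
    Deterministic given ``seed``.
    """
    X = np.asarray(features, float)
    Y = np.asarray(targets, float)
    if X.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise DataError("features and targets must be aligned 2-D arrays")
    n, n_in = X.shape
    n_out = Y.shape[1]
    n_par = n_hidden * (n_in + 1) + n_out * (n_hidden + 1)
    n_tr = int(round(n * (1 - val_frac)))
    Xtr_full, Ytr_full = X[:n_tr], Y[:n_tr]
    Xva, Yva = X[n_tr:], Y[n_tr:]
    stride = max(1, n_tr // max_train_samples)
    Xtr, Ytr = Xtr_full[::stride], Ytr_full[::stride]
    if Xtr.shape[0] < 10 * n_par / n_out and Xtr.shape[0] < n_tr:
        stride = 1
        Xtr, Ytr = Xtr_full, Ytr_full

    mean = Xtr.mean(axis=0)
    std = Xtr.std(axis=0)
    std = np.where(std > 1e-12, std, 1.0)
    Z = (Xtr - mean) / std
    Zva = (Xva - mean) / std if len(Xva) else Z[:0]

    rng = np.random.default_rng(seed)
    W1 = rng.normal(0, 1.0 / np.sqrt(n_in), size=(n_hidden, n_in))
    b1 = rng.normal(0, 0.1, size=n_hidden)
    W2 = rng.normal(0, 1.0 / np.sqrt(n_hidden), size=(n_out, n_hidden))
    b2 = Ytr.mean(axis=0)
    p = _pack(W1, b1, W2, b2)

    def cost(pvec, Zs, Ys):
        out, _ = _forward(_unpack(pvec, n_hidden, n_in, n_out), Zs)
        return out - Ys

    lam = 1e-2
    r = cost(p, Z, Ytr).ravel()
    best_val = np.inf
    best_p = p.copy()
    stall = 0
    converged = False
    for _ in range(max_iter):
        J = _jacobian(_unpack(p, n_hidden, n_in, n_out), Z)
        JtJ = J.T @ J
        g = J.T @ r
        accepted = False
        for _ in range(8):
            D = JtJ + lam * np.diag(np.maximum(np.diag(JtJ), 1e-10))
            try:
                step = np.linalg.solve(D, g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            p_new = p - step
            r_new = cost(p_new, Z, Ytr).ravel()
            if r_new @ r_new < r @ r:
                p, r = p_new, r_new
                lam = max(lam / 3.0, 1e-12)
                accepted = True
                break
            lam *= 3.0
        if not accepted:
            converged = True
            break
        if len(Zva):
            val_rmse = float(np.sqrt(np.mean(cost(p, Zva, Yva) ** 2)))
        else:
            val_rmse = float(np.sqrt(np.mean(r**2)))
        if val_rmse < best_val - 1e-9:
            best_val = val_rmse
            best_p = p.copy()
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
        if np.linalg.norm(g) < 1e-10:
            converged = True
            break

    W1, b1, W2, b2 = _unpack(best_p, n_hidden, n_in, n_out)
    train_rmse = float(np.sqrt(np.mean(cost(best_p, Z, Ytr) ** 2)))
    model = CoordinationModel(W1, b1, W2, b2, mean, std,
                              meta={"seed": seed, "n_hidden": n_hidden,
                                    "train_rmse": train_rmse,
                                    "val_rmse": best_val,
                                    "train_stride": stride,
                                    "converged": converged})
    return model


def predict_thigh(model: CoordinationModel, features: np.ndarray) -> np.ndarray:
    """Per-sample thigh (roll, pitch) in degrees for an (n, 11) feature
    matrix in the model's feature order."""
    X = np.asarray(features, float)
    if X.ndim != 2 or X.shape[1] != model.input_mean.size:
        raise DataError(
            f"expected (n, {model.input_mean.size}) features, got {X.shape}")
    Z = (X - model.input_mean) / model.input_std
    out, _ = _forward((model.W1, model.b1, model.W2, model.b2), Z)
    return out


def knee_angle(theta_t, theta_s, reference=None):
    """Knee angle ``beta = theta_t - theta_s`` (degrees) and, when a
    reference is given, the error series ``E_beta = beta - reference``."""
    theta_t = np.asarray(theta_t, float)
    theta_s = np.asarray(theta_s, float)
    if theta_t.shape != theta_s.shape:
        raise DataError("thigh and shank pitch series must be aligned")
    beta = theta_t - theta_s
    if reference is None:
        return beta
    reference = np.asarray(reference, float)
    if reference.shape != beta.shape:
        raise DataError("reference series must be aligned")
    return beta, beta - reference


def optimize_hidden_neurons(features, targets, candidates, seed: int = 0,
                            **train_kw):
    """Validation-RMSE curve over hidden-layer sizes.

    Trains one model per candidate (the same seed each time) and returns
    ``(n_best, rmse_curve)`` where ``n_best`` is the smallest candidate
    within 2% of the curve's minimum.
    """
    candidates = list(candidates)
    curve = []
    for n_hidden in candidates:
        m = train_coordination(features, targets, n_hidden=n_hidden,
                               seed=seed, **train_kw)
        curve.append(m.meta["val_rmse"])
    curve = np.asarray(curve)
    lo = curve.min()
    for n_hidden, rmse in zip(candidates, curve):
        if rmse <= 1.02 * lo:
            return n_hidden, curve
    return candidates[int(np.argmin(curve))], curve
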