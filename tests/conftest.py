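import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from limbflow.core_types import NoiseSpec
from limbflow.fusion_filter import run_fusion
from limbflow.motion_simulator import (
    GaitProfile,
    StrenuousProfile,
    generate_gait,
    generate_strenuous,
    sensorize,
)


@pytest.fixture(scope="session")
def gait_truth():
    """60 s gait sweep 0 -> 10 km/h (compressed schedule), seed 1."""
    return generate_gait(GaitProfile(hold_s=5.0), 60.0, seed=1)


@pytest.fixture(scope="session")
def strenuous_truth():
    """60 s strenuous burst run at the 120 m/s^2 peak target, seed 2."""
    return generate_strenuous(StrenuousProfile(), 60.0, seed=2)


@pytest.fixture(scope="session")
def gait_streams(gait_truth):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sensorize(gait_truth, NoiseSpec(seed=1))


@pytest.fixture(scope="session")
def gait_estimate(gait_streams):
    return run_fusion(gait_streams)


def fd_consistency_residual(truth):
    """Max interior residual of a_b - (omega x v_b + dv_b/dt) by central
    differences -- the independent finite-difference oracle."""
    v = truth.stack(("vx", "vy", "vz"))
    a = truth.stack(("ax", "ay", "az"))
    w = truth.stack(("wx", "wy", "wz"))
    vdot = np.gradient(v, truth.ts, axis=0)
    res = a - (np.cross(w, v) + vdot)
    return float(np.abs(res[2:-2]).max())
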