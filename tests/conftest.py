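import numpy as np
import pytest

from selfmotion import (
    Params,
    make_canal_model,
    make_neck_model,
    make_rotation_tilt_model,
    steady_state_gain,
)


@pytest.fixture(scope="session")
def params():
    return Params()


@pytest.fixture(scope="session")
def canal_model(params):
    return make_canal_model(params)


@pytest.fixture(scope="session")
def tilt_model(params):
    return make_rotation_tilt_model(params, gravity_coupled=True, include_otolith=True)


@pytest.fixture(scope="session")
def evar_model(params):
    return make_rotation_tilt_model(params, gravity_coupled=False, include_otolith=False)


@pytest.fixture(scope="session")
def neck_model(params):
    return make_neck_model(params)


@pytest.fixture(scope="session")
def canal_gain(canal_model):
    return steady_state_gain(canal_model)


@pytest.fixture(scope="session")
def tilt_gain(tilt_model):
    return steady_state_gain(tilt_model)


@pytest.fixture(scope="session")
def neck_gain(neck_model):
    return steady_state_gain(neck_model)


def time_varying_gain_oracle(model, n_steps=10**4):
    """Independent reference: run the time-varying Kalman recursion.

    Deliberately written differently from the package implementation:
    explicit innovation-covariance inverse and Joseph-form posterior
    update. Returns the per-step gain after ``n_steps`` from zero posterior
    covariance.
    """
    n = model.D.shape[0]
    P = np.zeros((n, n))
    I = np.eye(n)
    K = None
    for _ in range(n_steps):
        P_prior = model.D @ P @ model.D.T + model.E @ model.Q @ model.E.T
        innov = model.T @ P_prior @ model.T.T + model.R
        K = P_prior @ model.T.T @ np.linalg.inv(innov)
        A = I - K @ model.T
        P = A @ P_prior @ A.T + K @ model.R @ K.T  # Joseph form
    return K
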