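import numpy as np
import pytest

from psychodyn import (
    FluctuationSpec,
    InterventionSeries,
    ModelParameters,
    simulate,
)


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def untreated_run(default_params):
    """Noise-free untreated 64-week simulation from the canonical start."""
    u = InterventionSeries.none(64)
    latent, obs = simulate(default_params, u, x0=[8.0, 10.0, 32.0])
    return latent, obs, u


@pytest.fixture(scope="session")
def treated_run(default_params):
    """Noise-free simulation with a full-dose step intervention at week 32."""
    u = InterventionSeries.step(64, 32, dose=1.0)
    latent, obs = simulate(default_params, u, x0=[8.0, 10.0, 32.0])
    return latent, obs, u


@pytest.fixture(scope="session")
def noisy_run(default_params):
    """Low-noise untreated simulation (the package's reference noise levels)."""
    u = InterventionSeries.none(64)
    noise = FluctuationSpec(seed=11)
    latent, obs = simulate(default_params, u, x0=[8.0, 10.0, 32.0], noise=noise)
    return latent, obs, u


def kalman_rts(Y, A, C, Q, R, x0_mean, P0):
    """Independent Kalman filter / RTS smoother oracle with log-likelihood.

    Textbook implementation kept deliberately separate from the package's
    inversion machinery.
    """
    T = Y.shape[0]
    n = A.shape[0]
    m, P = np.asarray(x0_mean, float).copy(), np.asarray(P0, float).copy()
    ms, Ps, mp, Pp = [], [], [], []
    loglik = 0.0
    for t in range(T):
        S = C @ P @ C.T + R
        K = P @ C.T @ np.linalg.inv(S)
        innov = Y[t] - C @ m
        loglik += -0.5 * (
            innov @ np.linalg.solve(S, innov)
            + np.linalg.slogdet(2 * np.pi * S)[1]
        )
        m = m + K @ innov
        P = P - K @ C @ P
        ms.append(m.copy())
        Ps.append(P.copy())
        mp.append(A @ m)
        Pp.append(A @ P @ A.T + Q)
        m, P = mp[-1].copy(), Pp[-1].copy()
    sm = [None] * T
    sP = [None] * T
    sm[-1], sP[-1] = ms[-1], Ps[-1]
    for t in range(T - 2, -1, -1):
        G = Ps[t] @ A.T @ np.linalg.inv(Pp[t])
        sm[t] = ms[t] + G @ (sm[t + 1] - mp[t])
        sP[t] = Ps[t] + G @ (sP[t + 1] - Pp[t]) @ G.T
    means = np.asarray(sm)
    sds = np.sqrt(np.asarray([np.diag(p) for p in sP]))
    return means, sds, float(loglik)


@pytest.fixture(scope="session")
def linear_toy():
    """A simulated stable linear-Gaussian state-space realization."""
    rng = np.random.default_rng(0)
    A = 0.9 * np.array([[0.9, -0.2, 0.0], [0.2, 0.9, 0.0], [0.0, 0.0, 0.8]])
    C = np.array([[0.0, 1.0, 0.0], [0.0, 0.3, 0.7]])
    sq, so, T = 0.3, 0.1, 40
    x0_mean = np.array([1.0, 0.0, -1.0])
    x0_sd = np.full(3, 0.5)
    x = x0_mean + x0_sd * rng.standard_normal(3)
    X, Y = [x], []
    for t in range(T):
        Y.append(C @ X[-1] + so * rng.standard_normal(2))
        if t < T - 1:
            X.append(A @ X[-1] + sq * rng.standard_normal(3))
    return {
        "A": A, "C": C, "process_sd": sq, "obs_sd": so,
        "x0_mean": x0_mean, "x0_sd": x0_sd,
        "X": np.asarray(X), "Y": np.asarray(Y),
    }
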