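"""Generative model: Lorenz-form pathophysiology and clinical observation maps.

The latent pathophysiology x(t) follows Lorenz-form dynamics in which the
therapeutic input u attenuates the Rayleigh coupling; psychopathology v(t) is
a linear mixture of the last two pathophysiological states; symptoms are
sigmoid (tanh) functions of v and the differential diagnosis is a softmax of
the negative Euclidean distance from v to category-characteristic locations.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky
from scipy.special import softmax

from .types import (
    FluctuationSpec,
    InterventionSeries,
    LatentTrajectory,
    ModelParameters,
    NosologyMap,
    ObservationSeries,
    SubjectTraits,
)

__all__ = [
    "flow",
    "effective_rho",
    "map_psychopathology",
    "map_symptoms",
    "map_diagnosis",
    "sample_smooth_noise",
    "integrate_interval",
    "simulate",
    "IntegrationDivergence",
]

#: Fixed 4th-order Runge-Kutta sub-steps per assessment interval.
N_SUBSTEPS = 16

#: Integration guard: |x| beyond this is treated as numerical blow-up.
OVERFLOW_GUARD = 1e6


class IntegrationDivergence(RuntimeError):
    """Raised when the latent trajectory exceeds the overflow guard."""

    def __init__(self, time_index: int):
        self.time_index = time_index
        super().__init__(
            f"latent state diverged (overflow guard exceeded) at assessment "
            f"index {time_index}"
        )


def effective_rho(u: float | np.ndarray, traits: SubjectTraits) -> float | np.ndarray:
    """Dose-attenuated Rayleigh coupling rho * exp(-sensitivity * u).

    Monotone decreasing in the dose, equal to rho at u = 0 and approaching 0
    at large doses; for doses with rho_eff < 1 the chaotic attractor is
    replaced by a point attractor at the origin (remission).
    """
    return traits.rayleigh_rho * np.exp(-traits.intervention_sensitivity * np.asarray(u, float))


def flow(x: np.ndarray, u: float, traits: SubjectTraits) -> np.ndarray:
    """Instantaneous derivative dx/dt of the Lorenz-form pathophysiology.

    dx1 = sigma (x2 - x1)
    dx2 = x1 (rho_eff(u) - x3) - x2
    dx3 = x1 x2 - beta x3

    The derivative is in dynamical time units; one assessment interval spans
    ``traits.time_scale`` such units. The origin is a fixed point for every
    dose.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != 3 or not np.all(np.isfinite(x)) or not np.isfinite(u):
        raise ValueError(f"flow requires a finite 3-vector state and dose, got x={x!r} u={u!r}")
    rho_eff = effective_rho(u, traits)
    x1, x2, x3 = x[..., 0], x[..., 1], x[..., 2]
    return np.stack(
        [
            traits.rate_sigma * (x2 - x1),
            x1 * (rho_eff - x3) - x2,
            x1 * x2 - traits.geom_beta * x3,
        ],
        axis=-1,
    )


def map_psychopathology(x: np.ndarray, nosology: NosologyMap) -> np.ndarray:
    """Psychopathology v = mixing @ (x2, x3): a linear mixture of the last two states."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("map_psychopathology requires finite states")
    return x[..., 1:3] @ nosology.mixing.T


_SYM_CAP = 1.0 - 1e-12


def map_symptoms(v: np.ndarray, nosology: NosologyMap) -> np.ndarray:
    """Symptom scores s_i = tanh(loadings_i . v + offset_i), each in (-1, 1).

    Scores are kept strictly inside the open interval even where float
    rounding would saturate the sigmoid to +/-1.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("map_symptoms requires finite psychopathology")
    s = np.tanh(v @ nosology.symptom_loadings.T + nosology.symptom_offsets)
    return np.clip(s, -_SYM_CAP, _SYM_CAP)


def diagnostic_potential(v: np.ndarray, nosology: NosologyMap) -> np.ndarray:
    """Diagnostic potential: -precision * Euclidean distance to each category location."""
    v = np.asarray(v, dtype=float)
    diff = v[..., None, :] - nosology.diagnostic_locations  # (..., 4, 2)
    dist = np.sqrt(np.sum(diff**2, axis=-1))
    return -nosology.diagnostic_precision * dist


def map_diagnosis(v: np.ndarray, nosology: NosologyMap) -> np.ndarray:
    """Differential diagnosis: softmax of the diagnostic potential (4-simplex)."""
    if not np.all(np.isfinite(v)):
        raise ValueError("map_diagnosis requires finite psychopathology")
    return softmax(diagnostic_potential(v, nosology), axis=-1)


def sample_smooth_noise(
    T: int,
    dim: int,
    amplitude: float,
    correlation_length: float = 0.5,
    rng: np.random.Generator | int | None = None,
    dt: float = 1.0,
) -> np.ndarray:
    """Sample smooth stationary Gaussian fluctuations on a regular grid.

    Columns are independent zero-mean Gaussian processes with marginal
    standard deviation ``amplitude`` and squared-exponential autocorrelation
    exp(-tau^2 / (2 l^2)), l = ``correlation_length`` (assessment-interval
    units; default half an interval). ``dt`` is the grid spacing in the same
    units. Constructed by dense Cholesky factorization of the kernel matrix
    (series here are at most a few hundred points) with 1e-8 diagonal jitter.

    Returns a (T, dim) array; identically zero when ``amplitude`` is 0.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0.0:
        return np.zeros((T, dim))
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    tau = np.arange(T)[:, None] - np.arange(T)[None, :]
    K = np.exp(-((tau * dt) ** 2) / (2.0 * correlation_length**2))
    K[np.diag_indices(T)] += 1e-8
    L = cholesky(K, lower=True)
    return amplitude * (L @ rng.standard_normal((T, dim)))


def _noise_for_spec(
    T: int, dim: int, amplitude: float, spec: FluctuationSpec, rng: np.random.Generator
) -> np.ndarray:
    return sample_smooth_noise(
        T, dim, amplitude, correlation_length=spec.correlation_length, rng=rng
    )


def integrate_interval(
    x: np.ndarray,
    u: float | np.ndarray,
    traits: SubjectTraits,
    drift: np.ndarray | None = None,
    n_substeps: int = N_SUBSTEPS,
) -> np.ndarray:
    """Propagate the state over one assessment interval with fixed-step RK4.

    ``x`` may be a single 3-vector or an (n, 3) batch (``u`` then a scalar or
    length-n vector). ``drift`` is an optional additive perturbation to dx/dt
    (the pathophysiology-level fluctuation, held constant over the interval).
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    X = np.atleast_2d(x)
    U = np.broadcast_to(np.asarray(u, float), (X.shape[0],))
    rho_eff = effective_rho(U, traits)
    D = np.zeros_like(X) if drift is None else np.broadcast_to(drift, X.shape)
    h = traits.time_scale / n_substeps

    def f(Z: np.ndarray) -> np.ndarray:
        out = np.empty_like(Z)
        z1, z2, z3 = Z[:, 0], Z[:, 1], Z[:, 2]
        out[:, 0] = traits.rate_sigma * (z2 - z1)
        out[:, 1] = z1 * (rho_eff - z3) - z2
        out[:, 2] = z1 * z2 - traits.geom_beta * z3
        return out + D

    for _ in range(n_substeps):
        k1 = f(X)
        k2 = f(X + 0.5 * h * k1)
        k3 = f(X + 0.5 * h * k2)
        k4 = f(X + h * k3)
        X = X + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return X[0] if squeeze else X


def simulate(
    params: ModelParameters,
    u: InterventionSeries,
    x0: np.ndarray = (8.0, 10.0, 32.0),
    noise: FluctuationSpec | None = None,
) -> tuple[LatentTrajectory, ObservationSeries]:
    """Simulate a clinical trajectory over ``u.n_assessments`` assessments.

    The flow is integrated with fixed RK4 sub-steps per interval;
    pathophysiology-level fluctuations enter the equations of motion as a
    smooth per-interval drift, psychopathology-level fluctuations add to v,
    and outcome-level fluctuations add to the pre-sigmoid symptom predictor
    and the pre-softmax diagnostic potential (so that symptom scores remain
    in (-1, 1) and diagnoses on the simplex exactly). Deterministic given the
    fluctuation seed; with all amplitudes 0 the output equals the noiseless
    integration exactly.
    """
    if noise is None:
        noise = FluctuationSpec(amplitude_obs=0.0, amplitude_psy=0.0, amplitude_phys=0.0)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (3,) or not np.all(np.isfinite(x0)):
        raise ValueError("x0 must be a finite 3-vector")
    T = u.n_assessments
    rng = np.random.default_rng(noise.seed)
    w_phys = _noise_for_spec(T, 3, noise.amplitude_phys, noise, rng)
    w_psy = _noise_for_spec(T, 2, noise.amplitude_psy, noise, rng)
    w_sym = _noise_for_spec(T, 6, noise.amplitude_obs, noise, rng)
    w_diag = _noise_for_spec(T, 4, noise.amplitude_obs, noise, rng)

    nos = params.nosology
    X = np.empty((T, 3))
    X[0] = x0
    for t in range(T - 1):
        X[t + 1] = integrate_interval(X[t], u.values[t], params.traits, drift=w_phys[t])
        if not np.all(np.isfinite(X[t + 1])) or np.max(np.abs(X[t + 1])) > OVERFLOW_GUARD:
            raise IntegrationDivergence(t + 1)

    V = map_psychopathology(X, nos) + w_psy
    symptoms = np.clip(
        np.tanh(V @ nos.symptom_loadings.T + nos.symptom_offsets + w_sym),
        -_SYM_CAP,
        _SYM_CAP,
    )
    diagnosis = softmax(diagnostic_potential(V, nos) + w_diag, axis=-1)
    latent = LatentTrajectory(x=X, v=V)
    obs = ObservationSeries(symptoms=symptoms, diagnosis=diagnosis)
    return latent, obs
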