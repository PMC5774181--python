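"""Posterior-predictive prognosis and dose-response prediction.

Forecasts are built by sampling parameters and the final latent state from
a fitted subject posterior, integrating the generative model forward under
a hypothetical intervention schedule with process and outcome fluctuations,
and summarizing the sampled futures pointwise. The dose-response scan
repeats the forecast over a grid of constant doses and reports the
predictive probability that "remitted" is the modal diagnosis at a chosen
horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

from .inversion import PosteriorEstimate
from .model import diagnostic_potential, sample_smooth_noise
from .statespace import NonlinearDCM
from .types import InterventionSeries

__all__ = ["ForecastResult", "DoseResponseCurve", "forecast", "dose_response"]


@dataclass
class ForecastResult:
    """Pointwise predictive summaries over a forecast horizon.

    The central curves (``*_mean`` fields) are pointwise medians of the
    sampled futures — a robust centre for the heavy-tailed predictive
    densities chaotic dynamics produce — and the bands are central 90%
    intervals; diagnosis probabilities are summarized per category.
    """

    horizon: int
    state_mean: np.ndarray  # (H, 3)
    state_low: np.ndarray
    state_high: np.ndarray
    symptom_mean: np.ndarray  # (H, 6)
    symptom_low: np.ndarray
    symptom_high: np.ndarray
    diagnosis_mean: np.ndarray  # (H, 4)
    diagnosis_low: np.ndarray
    diagnosis_high: np.ndarray
    modal_diagnosis: np.ndarray  # (H,) most probable category of the mean
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.diagnosis_mean < -1e-9) or np.any(self.diagnosis_mean > 1 + 1e-9):
            raise ValueError("diagnosis predictive means must lie in [0, 1]")
        for lo, mid, hi in (
            (self.state_low, self.state_mean, self.state_high),
            (self.symptom_low, self.symptom_mean, self.symptom_high),
            (self.diagnosis_low, self.diagnosis_mean, self.diagnosis_high),
        ):
            if np.any(lo > mid + 1e-9) or np.any(mid > hi + 1e-9):
                raise ValueError("predictive bands must be ordered low <= mean <= high")


@dataclass
class DoseResponseCurve:
    """Predicted remission probability as a function of constant dose."""

    doses: np.ndarray
    remission_probability: np.ndarray
    horizon_assessment: int

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.remission_probability = np.asarray(self.remission_probability, dtype=float)
        if self.doses.shape != self.remission_probability.shape:
            raise ValueError("doses and probabilities must have equal length")
        if np.any((self.remission_probability < 0) | (self.remission_probability > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


def _integrate_batch(
    x: np.ndarray,
    u_t: float,
    sig: np.ndarray,
    rho: np.ndarray,
    beta: np.ndarray,
    sens: np.ndarray,
    tau: float,
    drift: np.ndarray,
    n_substeps: int = 16,
) -> np.ndarray:
    """RK4 over one interval with per-sample trait values."""
    rho_eff = rho * np.exp(-sens * u_t)
    h = tau / n_substeps

    def f(Z):
        z1, z2, z3 = Z[:, 0], Z[:, 1], Z[:, 2]
        return (
            np.stack(
                [sig * (z2 - z1), z1 * (rho_eff - z3) - z2, z1 * z2 - beta * z3],
                axis=1,
            )
            + drift
        )

    X = x
    for _ in range(n_substeps):
        k1 = f(X)
        k2 = f(X + 0.5 * h * k1)
        k3 = f(X + 0.5 * h * k2)
        k4 = f(X + h * k3)
        X = X + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return X


def _sample_futures(
    post: PosteriorEstimate,
    u_future: InterventionSeries,
    n_samples: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate sampled futures; returns (states, symptoms, diagnoses)."""
    H = u_future.n_assessments
    params = post.params_hat
    names = post.parameter_names
    mean = np.concatenate([post.state_means[-1], post.parameter_mean])
    cov = post.terminal_covariance
    # joint draw of the terminal state and the free parameters
    ev, E = np.linalg.eigh(0.5 * (cov + cov.T))
    A = E @ np.diag(np.sqrt(np.maximum(ev, 0.0)))
    draws = mean + rng.standard_normal((n_samples, mean.size)) @ A.T

    lam = post.log_precision_means
    q_sd = float(np.exp(-0.5 * lam.get("dynamic", np.inf)))
    obs_sd = float(np.exp(-0.5 * lam.get("outcome", np.inf)))

    nos = params.nosology
    traits = params.traits
    # per-sample trait values (sampled where free, fixed otherwise)
    trait_vals = {}
    for key in ("rate_sigma", "rayleigh_rho", "geom_beta", "intervention_sensitivity"):
        if key in names:
            trait_vals[key] = draws[:, 3 + names.index(key)]
        else:
            trait_vals[key] = np.full(n_samples, getattr(traits, key))
    mixing = np.broadcast_to(nos.mixing, (n_samples, 2, 2)).copy()
    for key, (i, j) in (
        ("mixing_v1_x2", (0, 0)), ("mixing_v1_x3", (0, 1)),
        ("mixing_v2_x2", (1, 0)), ("mixing_v2_x3", (1, 1)),
    ):
        if key in names:
            mixing[:, i, j] = draws[:, 3 + names.index(key)]

    # smooth process fluctuations, one independent series per sample and dim
    if q_sd > 0 and np.isfinite(q_sd):
        flat = sample_smooth_noise(
            H, 3 * n_samples, q_sd,
            correlation_length=NonlinearDCM.process_correlation_length,
            rng=rng,
        )
        drifts = flat.reshape(H, n_samples, 3)
    else:
        drifts = np.zeros((H, n_samples, 3))

    X = np.empty((n_samples, H, 3))
    x = draws[:, :3].copy()
    for t in range(H):
        X[:, t] = x
        if t < H - 1:
            x = _integrate_batch(
                x, float(u_future.values[t]),
                trait_vals["rate_sigma"], trait_vals["rayleigh_rho"],
                trait_vals["geom_beta"], trait_vals["intervention_sensitivity"],
                traits.time_scale, drifts[t],
            )
            x = np.clip(x, -1e6, 1e6)

    V = np.einsum("sij,stj->sti", mixing, X[..., 1:3])
    if obs_sd > 0 and np.isfinite(obs_sd):
        # psychopathology-level fluctuation (tied amplitude), then
        # outcome-level fluctuations on the pre-sigmoid and pre-softmax maps
        V = V + obs_sd * rng.standard_normal(V.shape)
        eps_s = obs_sd * rng.standard_normal((n_samples, H, 6))
        eps_d = obs_sd * rng.standard_normal((n_samples, H, 4))
    else:
        eps_s = 0.0
        eps_d = 0.0
    symptoms = np.tanh(V @ nos.symptom_loadings.T + nos.symptom_offsets + eps_s)
    pot = diagnostic_potential(V, nos) + eps_d
    diagnoses = softmax(pot, axis=-1)
    return X, symptoms, diagnoses


def forecast(
    post: PosteriorEstimate,
    u_future: InterventionSeries,
    n_samples: int = 512,
    seed: int = 0,
) -> ForecastResult:
    """Posterior-predictive forecast over ``u_future.n_assessments`` steps.

    Samples (terminal state, free parameters) from the joint posterior,
    integrates the generative dynamics forward under the hypothetical
    intervention with smooth process fluctuations at the inferred level,
    and maps each sampled trajectory through the observation model with
    outcome fluctuations. Deterministic given ``seed``.
    """
    if u_future.n_assessments < 1:
        raise ValueError("forecast horizon must be at least one assessment")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    X, symptoms, diagnoses = _sample_futures(post, u_future, n_samples, rng)

    def bands(arr):
        # the central curve is the pointwise median: chaotic futures are
        # heavy-tailed, where the mean can escape its own quantile band
        return (
            np.quantile(arr, 0.5, axis=0),
            np.quantile(arr, 0.05, axis=0),
            np.quantile(arr, 0.95, axis=0),
        )

    sm, sl, sh = bands(X)
    ym, yl, yh = bands(symptoms)
    dm, dl, dh = bands(diagnoses)
    return ForecastResult(
        horizon=u_future.n_assessments,
        state_mean=sm, state_low=sl, state_high=sh,
        symptom_mean=ym, symptom_low=yl, symptom_high=yh,
        diagnosis_mean=dm, diagnosis_low=dl, diagnosis_high=dh,
        modal_diagnosis=np.argmax(dm, axis=-1),
        n_samples=n_samples,
        seed=seed,
    )


def dose_response(
    post: PosteriorEstimate,
    doses: np.ndarray,
    start_assessment: int,
    horizon_assessment: int,
    n_samples: int = 512,
    seed: int = 0,
) -> DoseResponseCurve:
    """Predicted remission probability at the horizon for each dose.

    For each dose, forecasts with a step intervention beginning at
    ``start_assessment`` and computes the Monte-Carlo frequency with which
    "remitted" is the most probable diagnosis at ``horizon_assessment``.
    """
    doses = np.asarray(doses, dtype=float).ravel()
    if doses.size == 0:
        raise ValueError("dose grid must not be empty")
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if horizon_assessment <= start_assessment:
        raise ValueError("horizon must lie beyond the intervention start")
    probs = np.empty(doses.size)
    for i, dose in enumerate(doses):
        u = InterventionSeries.step(
            horizon_assessment + 1, start_assessment, dose=float(dose)
        )
        rng = np.random.default_rng(seed)
        _, _, diagnoses = _sample_futures(post, u, n_samples, rng)
        modal = np.argmax(diagnoses[:, horizon_assessment, :], axis=-1)
        probs[i] = float(np.mean(modal == 3))
    return DoseResponseCurve(
        doses=doses,
        remission_probability=probs,
        horizon_assessment=horizon_assessment,
    )
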