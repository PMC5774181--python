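"""Bijective transforms between constrained observations and Euclidean space.

The inversion scheme works in an unconstrained observation space: symptom
scores in (-1, 1) map through the inverse sigmoid (atanh) and the diagnostic
simplex maps through a log-ratio transform with "remitted" as the reference
category. Both transforms are exact inverses of the generative observation
nonlinearities, so additive Gaussian noise in the transformed space coincides
with where the generative model injects its outcome-level fluctuations.
"""

from __future__ import annotations

import numpy as np
from scipy.special import softmax

__all__ = [
    "diagnosis_to_unconstrained",
    "unconstrained_to_diagnosis",
    "symptoms_to_unconstrained",
    "unconstrained_to_symptoms",
    "DIAGNOSIS_CLIP",
    "SYMPTOM_CLIP",
]

#: Probabilities are clipped to at least this value before taking logs.
DIAGNOSIS_CLIP = 1e-6

#: Symptom scores are clipped into [-(1 - SYMPTOM_CLIP), 1 - SYMPTOM_CLIP].
SYMPTOM_CLIP = 1e-12


def diagnosis_to_unconstrained(delta: np.ndarray) -> np.ndarray:
    """Log-ratio transform of 4-category diagnostic probabilities.

    Returns ``z_i = log(delta_i / delta_ref)`` for the first three categories
    with the last category ("remitted") as reference; the uniform
    distribution maps to the origin. Entries are clipped at
    :data:`DIAGNOSIS_CLIP` so rows containing zeros transform finitely.
    """
    delta = np.clip(np.asarray(delta, dtype=float), DIAGNOSIS_CLIP, None)
    return np.log(delta[..., :3]) - np.log(delta[..., 3:4])


def unconstrained_to_diagnosis(z: np.ndarray) -> np.ndarray:
    """Inverse of :func:`diagnosis_to_unconstrained` (softmax with zero ref)."""
    z = np.asarray(z, dtype=float)
    full = np.concatenate([z, np.zeros(z.shape[:-1] + (1,))], axis=-1)
    return softmax(full, axis=-1)


def symptoms_to_unconstrained(s: np.ndarray) -> np.ndarray:
    """Inverse sigmoid (atanh) of symptom scores, clipped away from +/-1."""
    s = np.clip(np.asarray(s, dtype=float), -1 + SYMPTOM_CLIP, 1 - SYMPTOM_CLIP)
    return np.arctanh(s)


def unconstrained_to_symptoms(y: np.ndarray) -> np.ndarray:
    return np.tanh(np.asarray(y, dtype=float))
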