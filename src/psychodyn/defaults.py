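"""Frozen default parameterization of the generative model.

The latent flow uses the classic chaotic Lorenz rates (sigma = 10,
beta = 8/3, rho = 32). The default nosological mixing has the coupling from
the second pathophysiological state to the first psychopathological
construct set exactly to zero — the null coupling whose recovery and
exclusion by model reduction the group-level analyses demonstrate — while
the other three couplings are nonzero. Diagnostic-category locations place
"remitted" at the origin (the point attractor under full treatment) and the
F20 / F25 regions on either side of the band the untreated chaotic
trajectory sweeps through, so the untreated differential diagnosis
alternates between schizophrenia and schizoaffective disorder. Symptom
loadings are a unit-Gaussian draw frozen under :data:`LOADINGS_SEED`.
"""

from __future__ import annotations

import numpy as np

from .types import NosologyMap

__all__ = [
    "LOADINGS_SEED",
    "DEFAULT_MIXING",
    "DEFAULT_DIAGNOSTIC_LOCATIONS",
    "DEFAULT_DIAGNOSTIC_PRECISION",
    "DEFAULT_X0",
    "default_symptom_loadings",
    "default_nosology",
]

#: Seed of the frozen unit-Gaussian symptom-loading draw.
LOADINGS_SEED = 1

#: Nosological couplings (rows: v1, v2; columns: x2, x3). The x2 -> v1
#: coupling is the null coupling (exactly zero).
DEFAULT_MIXING = np.array([[0.0, 0.1], [0.125, 0.05]])

#: Category-characteristic locations in the psychopathology plane, ordered
#: (F20, F25, F32, remitted).
DEFAULT_DIAGNOSTIC_LOCATIONS = np.array(
    [[3.0, -1.0], [3.0, 3.5], [5.0, 1.0], [0.0, 0.0]]
)

DEFAULT_DIAGNOSTIC_PRECISION = 1.0

#: Default initial pathophysiological state.
DEFAULT_X0 = np.array([8.0, 10.0, 32.0])


def default_symptom_loadings() -> np.ndarray:
    """The frozen 6x2 unit-Gaussian symptom-loading matrix."""
    return np.random.default_rng(LOADINGS_SEED).standard_normal((6, 2))


def default_nosology() -> NosologyMap:
    """The default nosological mapping (fresh copy, safe to mutate)."""
    return NosologyMap(
        mixing=DEFAULT_MIXING.copy(),
        symptom_loadings=default_symptom_loadings(),
        symptom_offsets=np.zeros(6),
        diagnostic_locations=DEFAULT_DIAGNOSTIC_LOCATIONS.copy(),
        diagnostic_precision=DEFAULT_DIAGNOSTIC_PRECISION,
    )
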