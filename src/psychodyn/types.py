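"""Domain containers for the generative model of psychiatric trajectories.

The model distinguishes *traits* (time-invariant, subject-specific dynamical
parameters), the *nosology* (a mapping from latent pathophysiology to
psychopathology, symptoms and a categorical differential diagnosis that is
conserved over subjects), and *states* (the time-varying latent trajectory).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

__all__ = [
    "SubjectTraits",
    "NosologyMap",
    "InterventionSeries",
    "FluctuationSpec",
    "ModelParameters",
    "LatentTrajectory",
    "ObservationSeries",
    "DIAGNOSIS_NAMES",
    "SYMPTOM_NAMES",
]

#: ICD-10 categories of the modelled differential diagnosis, in canonical order.
#: The last category ("remitted") is the reference category of log-ratio
#: transforms and sits at the origin of the psychopathology plane by default.
DIAGNOSIS_NAMES = ("F20", "F25", "F32", "remitted")

#: The six normalized clinical instruments (five PANSS items plus the BDI).
SYMPTOM_NAMES = (
    "delusions",
    "disorganization",
    "blunted_affect",
    "withdrawal",
    "anxiety",
    "depression",
)


def _require_finite(name: str, value: np.ndarray | float) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass
class SubjectTraits:
    """Subject-specific dynamical traits of the pathophysiology flow.

    The latent pathophysiology follows Lorenz-form dynamics; ``rayleigh_rho``
    is the Rayleigh number controlling the state-dependent coupling from the
    first to the second state, which the therapeutic input attenuates with
    per-subject sensitivity ``intervention_sensitivity``.

    Parameters
    ----------
    rate_sigma : float
        Rate of relaxation of the first state toward the second.
    rayleigh_rho : float
        State-dependent coupling strength (Rayleigh number).
    geom_beta : float
        Dissipation rate of the third state.
    intervention_sensitivity : float
        Non-negative sensitivity to the therapeutic input; at 0 the flow is
        independent of the input.
    time_scale : float
        Dynamical time units elapsed per assessment interval (> 0).
    """

    rate_sigma: float = 10.0
    rayleigh_rho: float = 32.0
    geom_beta: float = 8.0 / 3.0
    intervention_sensitivity: float = 4.0
    time_scale: float = 0.5

    def __post_init__(self) -> None:
        for name in ("rate_sigma", "rayleigh_rho", "geom_beta",
                     "intervention_sensitivity", "time_scale"):
            _require_finite(name, getattr(self, name))
        if self.time_scale <= 0:
            raise ValueError("time_scale must be > 0")
        if self.intervention_sensitivity < 0:
            raise ValueError("intervention_sensitivity must be >= 0")


@dataclass
class NosologyMap:
    """Mapping from pathophysiology to psychopathology, symptoms and diagnosis.

    ``mixing`` rows index the two psychopathological constructs (v1, v2) and
    columns the second and third pathophysiological states (x2, x3); the four
    entries are the nosological couplings over which reduced models are
    defined. ``symptom_loadings`` and ``symptom_offsets`` parameterize the
    sigmoid (tanh) symptom model; ``diagnostic_locations`` are the four
    category-characteristic points in the psychopathology plane and
    ``diagnostic_precision`` the softmax inverse temperature applied to the
    negative Euclidean distances.
    """

    mixing: np.ndarray
    symptom_loadings: np.ndarray
    symptom_offsets: np.ndarray
    diagnostic_locations: np.ndarray
    diagnostic_precision: float = 1.0

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.symptom_loadings = np.asarray(self.symptom_loadings, dtype=float)
        self.symptom_offsets = np.asarray(self.symptom_offsets, dtype=float)
        self.diagnostic_locations = np.asarray(self.diagnostic_locations, dtype=float)
        if self.mixing.shape != (2, 2):
            raise ValueError("mixing must be 2x2")
        if self.symptom_loadings.shape != (6, 2):
            raise ValueError("symptom_loadings must be 6x2")
        if self.symptom_offsets.shape != (6,):
            raise ValueError("symptom_offsets must be a 6-vector")
        if self.diagnostic_locations.shape != (4, 2):
            raise ValueError("diagnostic_locations must be 4x2")
        for name in ("mixing", "symptom_loadings", "symptom_offsets",
                     "diagnostic_locations", "diagnostic_precision"):
            _require_finite(name, getattr(self, name))
        if self.diagnostic_precision <= 0:
            raise ValueError("diagnostic_precision must be > 0")
        d = self.diagnostic_locations
        for i in range(4):
            for j in range(i + 1, 4):
                if np.allclose(d[i], d[j]):
                    raise ValueError(
                        f"diagnostic_locations {i} and {j} coincide; categories "
                        "must occupy distinct points"
                    )


@dataclass
class InterventionSeries:
    """Per-assessment therapeutic input u(t) >= 0 (e.g. antipsychotic dose)."""

    values: np.ndarray
    n_assessments: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.n_assessments == 0:
            self.n_assessments = self.values.size
        if self.values.size != self.n_assessments:
            raise ValueError(
                f"length of values ({self.values.size}) != n_assessments "
                f"({self.n_assessments})"
            )
        if self.n_assessments < 1:
            raise ValueError("n_assessments must be positive")
        _require_finite("intervention values", self.values)
        if np.any(self.values < 0):
            raise ValueError("intervention values must be >= 0")

    @classmethod
    def step(cls, n_assessments: int, onset: int, dose: float = 1.0) -> "InterventionSeries":
        """A step intervention: 0 before ``onset``, ``dose`` from ``onset`` on."""
        u = np.zeros(n_assessments)
        u[onset:] = dose
        return cls(u)

    @classmethod
    def none(cls, n_assessments: int) -> "InterventionSeries":
        return cls(np.zeros(n_assessments))


@dataclass
class FluctuationSpec:
    """Smooth random fluctuations at the three levels of the model.

    Fluctuations are stationary Gaussian processes with a squared-exponential
    autocorrelation exp(-tau^2 / (2 l^2)) and correlation length ``l`` of half
    an assessment interval by default. Amplitudes are marginal standard
    deviations at the outcome (pre-sigmoid symptom / pre-softmax potential),
    psychopathology and pathophysiology levels; an amplitude of 0 switches
    that level's fluctuations off exactly.
    """

    amplitude_obs: float = 0.01
    amplitude_psy: float = 0.01
    amplitude_phys: float = 0.1
    correlation_length: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("amplitude_obs", "amplitude_psy", "amplitude_phys"):
            v = getattr(self, name)
            _require_finite(name, v)
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")


@dataclass
class ModelParameters:
    """All parameter groups of the generative model."""

    traits: SubjectTraits = field(default_factory=SubjectTraits)
    nosology: NosologyMap | None = None

    def __post_init__(self) -> None:
        if self.nosology is None:
            from .defaults import default_nosology

            self.nosology = default_nosology()

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            traits=replace(self.traits),
            nosology=NosologyMap(
                mixing=self.nosology.mixing.copy(),
                symptom_loadings=self.nosology.symptom_loadings.copy(),
                symptom_offsets=self.nosology.symptom_offsets.copy(),
                diagnostic_locations=self.nosology.diagnostic_locations.copy(),
                diagnostic_precision=self.nosology.diagnostic_precision,
            ),
        )


@dataclass
class LatentTrajectory:
    """Latent pathophysiology x(t) in R^3 and psychopathology v(t) in R^2."""

    x: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.x.ndim != 2 or self.x.shape[1] != 3:
            raise ValueError("x must be T x 3")
        if self.v.shape != (self.x.shape[0], 2):
            raise ValueError("v must be T x 2, aligned with x")
        _require_finite("x", self.x)
        _require_finite("v", self.v)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.x.shape[0])

    @property
    def n_assessments(self) -> int:
        return self.x.shape[0]


@dataclass
class ObservationSeries:
    """Observed symptom scores in (-1,1)^6 and diagnostic probabilities.

    Each diagnosis row is a probability distribution over the four categories
    (F20, F25, F32, remitted).
    """

    symptoms: np.ndarray
    diagnosis: np.ndarray

    def __post_init__(self) -> None:
        self.symptoms = np.asarray(self.symptoms, dtype=float)
        self.diagnosis = np.asarray(self.diagnosis, dtype=float)
        if self.symptoms.ndim != 2 or self.symptoms.shape[1] != 6:
            raise ValueError("symptoms must be T x 6")
        if self.diagnosis.shape != (self.symptoms.shape[0], 4):
            raise ValueError("diagnosis must be T x 4, aligned with symptoms")
        _require_finite("symptoms", self.symptoms)
        _require_finite("diagnosis", self.diagnosis)
        if np.any(np.abs(self.symptoms) >= 1):
            bad = np.unique(np.nonzero(np.abs(self.symptoms) >= 1)[0])
            raise ValueError(
                f"symptom scores must lie strictly in (-1, 1); offending "
                f"assessment indices: {bad.tolist()}"
            )
        if np.any(self.diagnosis < 0):
            raise ValueError("diagnosis probabilities must be >= 0")
        sums = self.diagnosis.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = np.nonzero(np.abs(sums - 1.0) > 1e-9)[0]
            raise ValueError(
                f"diagnosis rows must sum to 1; offending assessment "
                f"indices: {bad.tolist()}"
            )

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.symptoms.shape[0])

    @property
    def n_assessments(self) -> int:
        return self.symptoms.shape[0]

    def modal_diagnosis(self) -> np.ndarray:
        """Index of the most probable category at each assessment."""
        return np.argmax(self.diagnosis, axis=1)
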