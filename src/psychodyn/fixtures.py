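"""Seeded scenario bundles that make every pipeline stage testable on disk.

The fixtures mirror the package's canonical simulation studies: a treated
index patient (intervention at assessment 32 of 64), an untreated patient,
an eight-subject cohort sharing one nosology with subject-specific traits,
and a linear-Gaussian toy for smoother cross-checks. All outputs are
deterministic functions of (name, seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .defaults import DEFAULT_X0, default_nosology
from .inversion import PriorSpec
from .io import write_params, write_priors, write_timeseries
from .model import simulate
from .statespace import MIXING_NAMES
from .types import (
    FluctuationSpec,
    InterventionSeries,
    ModelParameters,
    SubjectTraits,
)

__all__ = ["make_fixture", "FIXTURE_NAMES", "cohort_priors", "COHORT_PRIOR_MIXING"]

FIXTURE_NAMES = (
    "index_patient",
    "untreated_patient",
    "cohort8",
    "linear_gaussian_toy",
)

#: Prior mean of the nosological mixing used when couplings are estimated:
#: a generic well-conditioned reference, deliberately different from the
#: default generating nosology so that recovery is data-driven.
COHORT_PRIOR_MIXING = np.array([[0.06, 0.12], [0.10, 0.03]])

#: Between-subject sd of the Rayleigh trait in the simulated cohort.
COHORT_RHO_SD = 1.0


def cohort_priors(x0_sd: float = 2.0) -> PriorSpec:
    """Priors for cohort inversion: free rho and all four couplings."""
    nos = default_nosology()
    nos.mixing = COHORT_PRIOR_MIXING.copy()
    base = ModelParameters(nosology=nos)
    return PriorSpec.for_model(
        base, free=("rayleigh_rho",) + MIXING_NAMES, x0_sd=x0_sd
    )


def _patient(out: Path, seed: int, treated: bool) -> None:
    params = ModelParameters()
    T = 64
    u = (
        InterventionSeries.step(T, 32, dose=1.0)
        if treated
        else InterventionSeries.none(T)
    )
    noise = FluctuationSpec(seed=seed)
    latent, obs = simulate(params, u, x0=DEFAULT_X0, noise=noise)
    write_params(
        out / "params.json",
        params,
        noise=noise,
        design={"n_assessments": T, "x0": DEFAULT_X0.tolist(),
                "intervention_onset": 32 if treated else None},
    )
    write_timeseries(out / "timeseries.csv", obs=obs, u=u, latent=latent)
    priors = PriorSpec.for_model(
        params, free=("rate_sigma", "rayleigh_rho", "geom_beta"), x0_sd=2.0
    )
    write_priors(out / "priors.json", priors)


def _cohort8(out: Path, seed: int) -> None:
    rng = np.random.default_rng(seed)
    nosology = default_nosology()
    T = 64
    manifest = {"subjects": [], "seed": seed}
    for i in range(8):
        rho_i = 32.0 + COHORT_RHO_SD * float(rng.standard_normal())
        traits = SubjectTraits(rayleigh_rho=rho_i)
        params = ModelParameters(traits=traits, nosology=nosology)
        u = InterventionSeries.none(T)
        noise = FluctuationSpec(seed=int(rng.integers(2**31)))
        latent, obs = simulate(params, u, x0=DEFAULT_X0, noise=noise)
        name = f"subject_{i:02d}.csv"
        write_timeseries(out / name, obs=obs, u=u)
        manifest["subjects"].append({"file": name, "rayleigh_rho": rho_i})
    write_params(out / "params.json", ModelParameters(nosology=nosology),
                 design={"n_assessments": T, "n_subjects": 8})
    write_priors(out / "priors.json", cohort_priors())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _linear_toy(out: Path, seed: int) -> None:
    rng = np.random.default_rng(seed)
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
    doc = {
        "format": "psychodyn-linear-toy-v1",
        "A": A.tolist(),
        "C": C.tolist(),
        "process_sd": sq,
        "obs_sd": so,
        "x0_mean": x0_mean.tolist(),
        "x0_sd": x0_sd.tolist(),
        "seed": seed,
        "X": np.asarray(X).tolist(),
        "Y": np.asarray(Y).tolist(),
    }
    (out / "linear_toy.json").write_text(json.dumps(doc, indent=2))


def make_fixture(name: str, out_dir, seed: int = 0) -> Path:
    """Write the named scenario bundle under ``out_dir``; returns its path."""
    if name not in FIXTURE_NAMES:
        raise ValueError(
            f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if name == "index_patient":
        _patient(out, seed, treated=True)
    elif name == "untreated_patient":
        _patient(out, seed, treated=False)
    elif name == "cohort8":
        _cohort8(out, seed)
    else:
        _linear_toy(out, seed)
    return out
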