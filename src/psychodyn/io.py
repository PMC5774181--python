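"""File formats: long-format clinical time series (CSV) and JSON configs.

All JSON documents carry a ``format`` tag; an unknown tag is a hard error,
never a silent coercion. The CSV dialect is long format with columns
``time,kind,name,value`` shared by symptoms, diagnoses, inputs and latent
states, so a single file can carry any subset of the model's series.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .inversion import ParamPrior, PosteriorEstimate, PriorSpec
from .types import (
    DIAGNOSIS_NAMES,
    SYMPTOM_NAMES,
    FluctuationSpec,
    InterventionSeries,
    LatentTrajectory,
    ModelParameters,
    NosologyMap,
    ObservationSeries,
    SubjectTraits,
)

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_params",
    "write_params",
    "read_priors",
    "write_priors",
    "read_posterior",
    "write_posterior",
    "SchemaError",
    "PARAMS_FORMAT",
    "PRIORS_FORMAT",
    "POSTERIOR_FORMAT",
]

PARAMS_FORMAT = "psychodyn-params-v1"
PRIORS_FORMAT = "psychodyn-priors-v1"
POSTERIOR_FORMAT = "psychodyn-posterior-v1"

_LATENT_X_NAMES = ("x1", "x2", "x3")
_LATENT_V_NAMES = ("v1", "v2")


class SchemaError(ValueError):
    """A file failed schema validation (missing columns, bad rows, bad tag)."""


def _check_format(doc: dict, expected: str, path) -> None:
    tag = doc.get("format")
    if tag != expected:
        raise SchemaError(
            f"{path}: unknown or missing format tag {tag!r} (expected {expected!r})"
        )


# --------------------------------------------------------------------------
# long-format time series


def write_timeseries(
    path,
    obs: ObservationSeries | None = None,
    u: InterventionSeries | None = None,
    latent: LatentTrajectory | None = None,
) -> None:
    """Write any subset of the model's series as long-format CSV."""
    rows: list[tuple[int, str, str, float]] = []
    if obs is not None:
        for t in range(obs.n_assessments):
            for j, name in enumerate(SYMPTOM_NAMES):
                rows.append((t, "symptom", name, obs.symptoms[t, j]))
            for j, name in enumerate(DIAGNOSIS_NAMES):
                rows.append((t, "diagnosis", name, obs.diagnosis[t, j]))
    if u is not None:
        for t in range(u.n_assessments):
            rows.append((t, "input", "dose", u.values[t]))
    if latent is not None:
        for t in range(latent.n_assessments):
            for j, name in enumerate(_LATENT_X_NAMES):
                rows.append((t, "latent_x", name, latent.x[t, j]))
            for j, name in enumerate(_LATENT_V_NAMES):
                rows.append((t, "latent_v", name, latent.v[t, j]))
    if not rows:
        raise ValueError("nothing to write")
    df = pd.DataFrame(rows, columns=["time", "kind", "name", "value"])
    df.to_csv(path, index=False, float_format="%.17g")


def _pivot(df: pd.DataFrame, kind: str, names: tuple[str, ...], path) -> np.ndarray | None:
    sub = df[df["kind"] == kind]
    if sub.empty:
        return None
    missing = set(names) - set(sub["name"].unique())
    if missing:
        raise SchemaError(f"{path}: kind {kind!r} is missing series {sorted(missing)}")
    wide = sub.pivot_table(index="time", columns="name", values="value")
    times = wide.index.to_numpy()
    if not np.array_equal(times, np.arange(len(times))):
        raise SchemaError(
            f"{path}: kind {kind!r} must cover assessment indices 0..T-1 "
            "without gaps"
        )
    return wide[list(names)].to_numpy()


def read_timeseries(path) -> tuple[ObservationSeries, InterventionSeries]:
    """Read a clinical series (symptoms + diagnosis + input) from CSV.

    Validates the simplex and range invariants on load and reports the
    offending assessment indices.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: not a readable CSV ({exc})") from exc
    required = {"time", "kind", "name", "value"}
    if set(df.columns) < required:
        raise SchemaError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    if df.empty:
        raise SchemaError(f"{path}: file contains no rows")
    symptoms = _pivot(df, "symptom", SYMPTOM_NAMES, path)
    diagnosis = _pivot(df, "diagnosis", DIAGNOSIS_NAMES, path)
    if symptoms is None or diagnosis is None:
        raise SchemaError(f"{path}: both symptom and diagnosis series are required")
    bad = np.nonzero(np.abs(diagnosis.sum(axis=1) - 1.0) > 1e-6)[0]
    if bad.size:
        raise SchemaError(
            f"{path}: diagnosis rows do not sum to 1 at assessment indices "
            f"{bad.tolist()}"
        )
    bad = np.unique(np.nonzero(np.abs(symptoms) > 1)[0])
    if bad.size:
        raise SchemaError(
            f"{path}: symptom scores outside [-1, 1] at assessment indices "
            f"{bad.tolist()}"
        )
    # renormalize away float round-off, then clip strictly inside the
    # open interval required by the in-memory container
    diagnosis = np.clip(diagnosis, 0.0, None)
    diagnosis = diagnosis / diagnosis.sum(axis=1, keepdims=True)
    symptoms = np.clip(symptoms, -1 + 1e-12, 1 - 1e-12)
    obs = ObservationSeries(symptoms=symptoms, diagnosis=diagnosis)
    dose = _pivot(df, "input", ("dose",), path)
    if dose is None:
        u = InterventionSeries.none(obs.n_assessments)
    else:
        if dose.shape[0] != obs.n_assessments:
            raise SchemaError(f"{path}: input series length mismatch")
        u = InterventionSeries(dose[:, 0])
    return obs, u


def read_latent(path) -> LatentTrajectory:
    """Read latent trajectories (x and v) from a long-format CSV."""
    df = pd.read_csv(path)
    x = _pivot(df, "latent_x", _LATENT_X_NAMES, path)
    v = _pivot(df, "latent_v", _LATENT_V_NAMES, path)
    if x is None or v is None:
        raise SchemaError(f"{path}: latent_x and latent_v series are required")
    return LatentTrajectory(x=x, v=v)


# --------------------------------------------------------------------------
# parameter / design documents


def write_params(
    path,
    params: ModelParameters,
    noise: FluctuationSpec | None = None,
    design: dict | None = None,
) -> None:
    """Write a full model configuration (traits, nosology, noise, design)."""
    nos = params.nosology
    doc = {
        "format": PARAMS_FORMAT,
        "traits": asdict(params.traits),
        "nosology": {
            "mixing": nos.mixing.tolist(),
            "symptom_loadings": nos.symptom_loadings.tolist(),
            "symptom_offsets": nos.symptom_offsets.tolist(),
            "diagnostic_locations": nos.diagnostic_locations.tolist(),
            "diagnostic_precision": nos.diagnostic_precision,
        },
        "fluctuations": asdict(noise) if noise is not None else None,
        "design": design or {},
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_params(path) -> tuple[ModelParameters, FluctuationSpec | None, dict]:
    doc = json.loads(Path(path).read_text())
    _check_format(doc, PARAMS_FORMAT, path)
    params = ModelParameters(
        traits=SubjectTraits(**doc["traits"]),
        nosology=NosologyMap(
            mixing=np.array(doc["nosology"]["mixing"]),
            symptom_loadings=np.array(doc["nosology"]["symptom_loadings"]),
            symptom_offsets=np.array(doc["nosology"]["symptom_offsets"]),
            diagnostic_locations=np.array(doc["nosology"]["diagnostic_locations"]),
            diagnostic_precision=doc["nosology"]["diagnostic_precision"],
        ),
    )
    noise = (
        FluctuationSpec(**doc["fluctuations"])
        if doc.get("fluctuations") is not None
        else None
    )
    return params, noise, doc.get("design", {})


def write_priors(path, priors: PriorSpec) -> None:
    doc = {
        "format": PRIORS_FORMAT,
        "parameters": {
            name: asdict(entry) for name, entry in priors.parameters.items()
        },
        "x0_mean": priors.x0_mean.tolist(),
        "x0_sd": priors.x0_sd.tolist(),
        "log_precisions": {
            name: asdict(entry) for name, entry in priors.log_precisions.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_priors(path) -> PriorSpec:
    doc = json.loads(Path(path).read_text())
    _check_format(doc, PRIORS_FORMAT, path)
    return PriorSpec(
        parameters={
            name: ParamPrior(**entry) for name, entry in doc["parameters"].items()
        },
        x0_mean=np.array(doc["x0_mean"]),
        x0_sd=np.array(doc["x0_sd"]),
        log_precisions={
            name: ParamPrior(**entry)
            for name, entry in doc["log_precisions"].items()
        },
    )


def write_posterior(path, post: PosteriorEstimate) -> None:
    params = post.params_hat
    nos = params.nosology
    doc = {
        "format": POSTERIOR_FORMAT,
        "state_means": post.state_means.tolist(),
        "state_sds": post.state_sds.tolist(),
        "parameter_names": list(post.parameter_names),
        "parameter_mean": post.parameter_mean.tolist(),
        "parameter_covariance": post.parameter_covariance.tolist(),
        "evidence": post.evidence,
        "evidence_trace": post.evidence_trace.tolist(),
        "converged": post.converged,
        "n_iterations": post.n_iterations,
        "log_precision_means": post.log_precision_means,
        "log_precision_sds": post.log_precision_sds,
        "parameter_prior_mean": post.parameter_prior_mean.tolist(),
        "parameter_prior_covariance": post.parameter_prior_covariance.tolist(),
        "terminal_covariance": post.terminal_covariance.tolist(),
        "params_hat": {
            "traits": asdict(params.traits),
            "nosology": {
                "mixing": nos.mixing.tolist(),
                "symptom_loadings": nos.symptom_loadings.tolist(),
                "symptom_offsets": nos.symptom_offsets.tolist(),
                "diagnostic_locations": nos.diagnostic_locations.tolist(),
                "diagnostic_precision": nos.diagnostic_precision,
            },
        },
        "u": post.u.values.tolist() if post.u is not None else None,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_posterior(path) -> PosteriorEstimate:
    doc = json.loads(Path(path).read_text())
    _check_format(doc, POSTERIOR_FORMAT, path)
    ph = doc["params_hat"]
    params = ModelParameters(
        traits=SubjectTraits(**ph["traits"]),
        nosology=NosologyMap(
            mixing=np.array(ph["nosology"]["mixing"]),
            symptom_loadings=np.array(ph["nosology"]["symptom_loadings"]),
            symptom_offsets=np.array(ph["nosology"]["symptom_offsets"]),
            diagnostic_locations=np.array(ph["nosology"]["diagnostic_locations"]),
            diagnostic_precision=ph["nosology"]["diagnostic_precision"],
        ),
    )
    u = (
        InterventionSeries(np.array(doc["u"]))
        if doc.get("u") is not None
        else None
    )
    return PosteriorEstimate(
        state_means=np.array(doc["state_means"]),
        state_sds=np.array(doc["state_sds"]),
        parameter_names=tuple(doc["parameter_names"]),
        parameter_mean=np.array(doc["parameter_mean"]),
        parameter_covariance=np.array(doc["parameter_covariance"]),
        evidence=doc["evidence"],
        evidence_trace=np.array(doc["evidence_trace"]),
        converged=doc["converged"],
        n_iterations=doc["n_iterations"],
        log_precision_means=doc["log_precision_means"],
        log_precision_sds=doc["log_precision_sds"],
        parameter_prior_mean=np.array(doc["parameter_prior_mean"]),
        parameter_prior_covariance=np.array(doc["parameter_prior_covariance"]),
        params_hat=params,
        terminal_covariance=np.array(doc["terminal_covariance"]),
        u=u,
    )
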