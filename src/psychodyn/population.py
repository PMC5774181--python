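"""Group-level inference: empirical Bayes, model enumeration and reduction.

Nosological parameters are fixed effects conserved over subjects: the group
posterior fuses each subject's Gaussian posterior update under the shared
prior. Subject traits are random effects summarized by a population mean
and between-subject spread. Hypotheses about which nosological couplings
exist are scored without refitting via Bayesian model reduction: the
analytic evidence adjustment obtained by replacing the full prior with a
reduced one (excluded couplings pinned near zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.base import BaseEstimator

from .inversion import (
    InversionSettings,
    PosteriorEstimate,
    PriorSpec,
    SubjectDCM,
)
from .statespace import MIXING_NAMES
from .types import InterventionSeries, ModelParameters, ObservationSeries

__all__ = [
    "GaussianDensity",
    "GroupPosterior",
    "ReducedModelSpec",
    "EmpiricalBayesGroup",
    "empirical_bayes",
    "enumerate_reduced_models",
    "bayesian_model_reduction",
    "model_posterior",
    "reduce_group_nosology",
    "REDUCED_PRIOR_SD",
]

#: Prior sd that stands in for excluding a coupling (a numerically stable
#: delta prior at zero).
REDUCED_PRIOR_SD = 1e-4


@dataclass
class GaussianDensity:
    """A multivariate Gaussian given by mean and covariance."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        d = self.mean.size
        if self.cov.shape != (d, d):
            raise ValueError("covariance shape does not match mean")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.min(np.linalg.eigvalsh((self.cov + self.cov.T) / 2)) < -1e-10:
            raise ValueError("covariance must be positive semi-definite")

    @property
    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.cov)


@dataclass
class ReducedModelSpec:
    """One of the 16 nosological hypotheses: an inclusion mask over couplings.

    The mask follows the canonical coupling order (x2->v1, x3->v1, x2->v2,
    x3->v2); ``index`` = 1 + sum(mask_i * 2^(i-1)).
    """

    mask: tuple[bool, bool, bool, bool]
    index: int = 0

    def __post_init__(self) -> None:
        self.mask = tuple(bool(m) for m in self.mask)
        if len(self.mask) != 4:
            raise ValueError("mask must cover the four nosological couplings")
        canonical = 1 + sum(int(m) << i for i, m in enumerate(self.mask))
        if self.index == 0:
            self.index = canonical
        elif self.index != canonical:
            raise ValueError(
                f"index {self.index} inconsistent with mask {self.mask} "
                f"(canonical {canonical})"
            )

    @property
    def included_names(self) -> tuple[str, ...]:
        return tuple(n for n, m in zip(MIXING_NAMES, self.mask) if m)

    @property
    def excluded_names(self) -> tuple[str, ...]:
        return tuple(n for n, m in zip(MIXING_NAMES, self.mask) if not m)


def enumerate_reduced_models() -> list[ReducedModelSpec]:
    """All 2^4 = 16 inclusion patterns over the nosological couplings."""
    specs = []
    for bits in product((False, True), repeat=4):
        specs.append(ReducedModelSpec(mask=bits))
    specs.sort(key=lambda s: s.index)
    return specs


def bayesian_model_reduction(
    full_prior: GaussianDensity,
    full_posterior: GaussianDensity,
    reduced_prior: GaussianDensity,
) -> tuple[float, GaussianDensity]:
    """Analytic evidence change and posterior under a reduced prior.

    Given the full model's prior p0 = N(m0, C0) and posterior q = N(mq, Cq)
    and a reduced prior pr over the same parameters, returns
    (log Z_r - log Z_0, reduced posterior) without re-inverting the data:

        P_rq = Pq + Pr - P0,    m_rq = P_rq^-1 (Pq mq + Pr mr - P0 m0)
        dF = 1/2 [ log|Pq| + log|Pr| - log|P0| - log|P_rq| ]
           + 1/2 [ m_rq' P_rq m_rq - mq' Pq mq - mr' Pr mr + m0' P0 m0 ]
    """
    P0, Pq, Pr = full_prior.precision, full_posterior.precision, reduced_prior.precision
    m0, mq, mr = full_prior.mean, full_posterior.mean, reduced_prior.mean
    Prq = Pq + Pr - P0
    ev = np.linalg.eigvalsh((Prq + Prq.T) / 2)
    if np.min(ev) <= 0:
        raise ValueError(
            "reduced-posterior precision is not positive definite; the "
            "reduction is incompatible with the full posterior"
        )
    eta = Pq @ mq + Pr @ mr - P0 @ m0
    Crq = np.linalg.inv(Prq)
    mrq = Crq @ eta
    logdets = (
        np.linalg.slogdet(Pq)[1]
        + np.linalg.slogdet(Pr)[1]
        - np.linalg.slogdet(P0)[1]
        - np.linalg.slogdet(Prq)[1]
    )
    quad = (
        mrq @ Prq @ mrq
        - mq @ Pq @ mq
        - mr @ Pr @ mr
        + m0 @ P0 @ m0
    )
    dF = 0.5 * float(logdets + quad)
    return dF, GaussianDensity(mean=mrq, cov=0.5 * (Crq + Crq.T))


def model_posterior(log_evidences: np.ndarray) -> np.ndarray:
    """Posterior model probabilities under a flat prior over models."""
    le = np.asarray(log_evidences, dtype=float)
    if not np.all(np.isfinite(le)):
        raise ValueError("log evidences must be finite")
    le = le - np.max(le)
    w = np.exp(le)
    return w / w.sum()


@dataclass
class GroupPosterior:
    """Empirical-Bayes group posterior over shared nosological parameters."""

    shared_names: tuple[str, ...]
    group_mean: np.ndarray
    group_covariance: np.ndarray
    group_prior: GaussianDensity
    subject_posteriors: list[PosteriorEstimate]
    group_evidence: float
    random_effects: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        C = self.group_covariance
        if not np.allclose(C, C.T, atol=1e-8) or np.min(
            np.linalg.eigvalsh((C + C.T) / 2)
        ) < -1e-8:
            raise ValueError("group covariance must be symmetric PSD")

    def interval90(self) -> tuple[np.ndarray, np.ndarray]:
        sd = np.sqrt(np.diag(self.group_covariance))
        return self.group_mean - 1.645 * sd, self.group_mean + 1.645 * sd

    @property
    def posterior_density(self) -> GaussianDensity:
        return GaussianDensity(self.group_mean, self.group_covariance)


def _gauss_log_normalizer(P: np.ndarray, eta: np.ndarray) -> float:
    """log integral of exp(-1/2 x'Px + eta'x)."""
    d = eta.size
    sign, logdet = np.linalg.slogdet(P)
    return 0.5 * (
        float(eta @ np.linalg.solve(P, eta)) + d * np.log(2 * np.pi) - logdet
    )


class EmpiricalBayesGroup(BaseEstimator):
    """Hierarchical (empirical Bayes) estimation across subjects.

    Shared (nosological) parameters are fixed effects: each subject's
    Gaussian posterior update over them is fused under the common prior.
    Remaining free parameters are subject-specific random effects whose
    population mean and between-subject sd are summarized with a
    weakly-informative log-precision prior N(0, 1).

    Attributes
    ----------
    group_ : GroupPosterior
    """

    def __init__(
        self,
        priors: PriorSpec,
        shared: tuple[str, ...] = MIXING_NAMES,
        settings: InversionSettings | None = None,
        base_params: ModelParameters | None = None,
    ):
        self.priors = priors
        self.shared = shared
        self.settings = settings
        self.base_params = base_params

    def fit(
        self,
        subject_data: list[tuple[ObservationSeries, InterventionSeries]],
    ) -> "EmpiricalBayesGroup":
        if not subject_data:
            raise ValueError("at least one subject is required")
        free = self.priors.free_names
        shared = tuple(n for n in free if n in self.shared)
        if set(self.shared) - set(free):
            raise ValueError(
                "shared parameters must be free in the priors: missing "
                f"{sorted(set(self.shared) - set(free))}"
            )
        posts = []
        n_excluded = 0
        for obs, u in subject_data:
            est = SubjectDCM(
                priors=self.priors,
                settings=self.settings,
                base_params=self.base_params,
            )
            post = est.fit(obs, u).posterior_
            if post.converged:
                posts.append(post)
            else:
                n_excluded += 1
        if not posts:
            raise RuntimeError(
                "no subject inversion converged; cannot form a group posterior"
            )
        if n_excluded:
            warnings.warn(
                f"excluded {n_excluded} non-converged subject fit(s) from the "
                "group posterior",
                RuntimeWarning,
            )

        names = posts[0].parameter_names
        idx = np.array([names.index(n) for n in shared])
        prior_mean = posts[0].parameter_prior_mean[idx]
        prior_cov = posts[0].parameter_prior_covariance[np.ix_(idx, idx)]
        P0 = np.linalg.inv(prior_cov)
        eta0 = P0 @ prior_mean

        # fixed-effects fusion: group posterior ~ prior * prod_i (q_i / p0)
        Pg = P0.copy()
        etag = eta0.copy()
        log_c = 0.0  # group-evidence bookkeeping
        for post in posts:
            Ci = post.parameter_covariance[np.ix_(idx, idx)]
            Pi = np.linalg.inv(Ci)
            mi = post.parameter_mean[idx]
            Pg += Pi - P0
            etag += Pi @ mi - eta0
            # subject evidence = log c_i + psi(Pi_like + P0, ...) terms; the
            # fusion correction below needs only the likelihood factors
            log_c += post.evidence - (
                _gauss_log_normalizer(Pi, Pi @ mi)
                - _gauss_log_normalizer(P0, eta0)
            )
        ev = np.linalg.eigvalsh((Pg + Pg.T) / 2)
        if np.min(ev) <= 0:
            raise ValueError("group precision not positive definite")
        Cg = np.linalg.inv(Pg)
        mg = Cg @ etag
        group_evidence = log_c + _gauss_log_normalizer(Pg, etag) - _gauss_log_normalizer(
            P0, eta0
        )

        # random-effects summary over non-shared free traits
        random_effects = {}
        for name in free:
            if name in shared:
                continue
            k = names.index(name)
            means = np.array([p.parameter_mean[k] for p in posts])
            wvars = np.array([p.parameter_covariance[k, k] for p in posts])
            random_effects[name] = _random_effect_summary(means, wvars)

        self.group_ = GroupPosterior(
            shared_names=shared,
            group_mean=mg,
            group_covariance=0.5 * (Cg + Cg.T),
            group_prior=GaussianDensity(prior_mean, prior_cov),
            subject_posteriors=posts,
            group_evidence=float(group_evidence),
            random_effects=random_effects,
        )
        return self


def _random_effect_summary(
    means: np.ndarray, within_vars: np.ndarray
) -> tuple[float, float]:
    """Population mean and between-subject sd of one random-effect trait.

    Maximizes the marginal likelihood of the subject posterior means over a
    log-precision grid, regularized by a weakly-informative N(0, 1) prior on
    the log between-subject precision.
    """
    mu = float(np.mean(means))
    log_tau_grid = np.linspace(-6, 6, 121)
    best = (-np.inf, 0.0)
    for lt in log_tau_grid:
        sb2 = np.exp(-lt)
        var = sb2 + within_vars
        ll = -0.5 * np.sum((means - mu) ** 2 / var + np.log(2 * np.pi * var))
        ll += -0.5 * lt**2  # N(0,1) prior on log tau
        if ll > best[0]:
            best = (ll, lt)
    return mu, float(np.exp(-best[1] / 2))


def empirical_bayes(
    subject_data: list[tuple[ObservationSeries, InterventionSeries]],
    priors: PriorSpec,
    shared: tuple[str, ...] = MIXING_NAMES,
    settings: InversionSettings | None = None,
    base_params: ModelParameters | None = None,
) -> GroupPosterior:
    """Group posterior over shared nosological parameters (fixed effects)."""
    est = EmpiricalBayesGroup(
        priors=priors, shared=shared, settings=settings, base_params=base_params
    )
    return est.fit(subject_data).group_


def reduce_group_nosology(
    group: GroupPosterior,
) -> tuple[list[ReducedModelSpec], np.ndarray, np.ndarray]:
    """Score all 16 nosological hypotheses by Bayesian model reduction.

    Returns (specs, delta-log-evidences, posterior model probabilities);
    excluded couplings get a reduced prior N(0, REDUCED_PRIOR_SD^2).
    """
    if set(group.shared_names) != set(MIXING_NAMES):
        raise ValueError(
            "model reduction over nosological couplings requires all four "
            "couplings to be shared free parameters"
        )
    order = [group.shared_names.index(n) for n in MIXING_NAMES]
    prior = group.group_prior
    posterior = group.posterior_density
    specs = enumerate_reduced_models()
    dFs = np.empty(len(specs))
    for i, spec in enumerate(specs):
        mr = prior.mean.copy()
        Cr = prior.cov.copy()
        for j, included in enumerate(spec.mask):
            if not included:
                k = order[j]
                mr[k] = 0.0
                Cr[k, :] = 0.0
                Cr[:, k] = 0.0
                Cr[k, k] = REDUCED_PRIOR_SD**2
        dFs[i], _ = bayesian_model_reduction(
            prior, posterior, GaussianDensity(mr, Cr)
        )
    return specs, dFs, model_posterior(dFs)
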