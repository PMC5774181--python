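"""Dual-estimation tests: oracle equivalence, recovery, evidence behaviour."""

import warnings

import numpy as np
import pytest

from psychodyn import (
    FluctuationSpec,
    InterventionSeries,
    ModelParameters,
    ParamPrior,
    PriorSpec,
    InversionSettings,
    SubjectTraits,
    invert_subject,
    log_evidence,
    map_diagnosis,
    map_psychopathology,
    simulate,
)
from psychodyn.inversion import LaplaceProblem
from psychodyn.statespace import LinearGaussianSSM
from psychodyn.transforms import (
    diagnosis_to_unconstrained,
    unconstrained_to_diagnosis,
)

from conftest import kalman_rts


class TestKalmanOracle:
    """In the linear-Gaussian limit the scheme is the Kalman/RTS smoother."""

    def _invert(self, toy):
        model = LinearGaussianSSM(toy["A"], toy["C"])
        priors = PriorSpec(
            parameters={},
            x0_mean=toy["x0_mean"],
            x0_sd=toy["x0_sd"],
            log_precisions={
                "obs": ParamPrior(-2 * np.log(toy["obs_sd"])),
                "dynamic": ParamPrior(-2 * np.log(toy["process_sd"])),
            },
        )
        T = toy["Y"].shape[0]
        problem = LaplaceProblem(
            model, toy["Y"], np.zeros(T), priors, InversionSettings()
        )
        return problem.solve()

    def test_states_and_evidence_match_rts_smoother(self, linear_toy):
        sol = self._invert(linear_toy)
        means, sds, loglik = kalman_rts(
            linear_toy["Y"],
            linear_toy["A"],
            linear_toy["C"],
            linear_toy["process_sd"] ** 2 * np.eye(3),
            linear_toy["obs_sd"] ** 2 * np.eye(2),
            linear_toy["x0_mean"],
            np.diag(linear_toy["x0_sd"] ** 2),
        )
        assert np.max(np.abs(sol["X"] - means)) < 1e-3
        assert np.max(np.abs(sol["state_sds"] - sds)) < 1e-3
        assert sol["evidence"] == pytest.approx(loglik, abs=1e-3)


class TestStateRecovery:
    def test_zero_noise_states_recovered(self, default_params, untreated_run):
        """Noise-free data with parameters pinned at truth: the trajectory is
        recovered to well under a tenth of a state unit."""
        latent, obs, u = untreated_run
        priors = PriorSpec.for_model(
            default_params, free=(), estimate_precisions=False,
            x0_mean=[9.0, 9.0, 30.0], x0_sd=1.0,
        )
        post = invert_subject(obs, u, priors)
        rmse = np.sqrt(np.mean((post.state_means - latent.x) ** 2, axis=0))
        assert np.all(rmse < 0.1)

    def test_interval_accessor_is_mean_pm_1645_sd(
        self, default_params, untreated_run
    ):
        latent, obs, u = untreated_run
        priors = PriorSpec.for_model(default_params, free=(), x0_sd=1.0)
        post = invert_subject(obs, u, priors)
        lo, hi = post.state_interval90()
        assert np.allclose(hi - post.state_means, 1.645 * post.state_sds)
        assert np.allclose(post.state_means - lo, 1.645 * post.state_sds)

    def test_treated_inversion_recovers_remission(self, default_params):
        """Inverting a treated series reproduces the collapse to the point
        attractor and a modal diagnosis of remission at the end."""
        u = InterventionSeries.step(64, 32, dose=1.0)
        _, obs = simulate(
            default_params, u, noise=FluctuationSpec(seed=3)
        )
        priors = PriorSpec.for_model(
            default_params, free=("rayleigh_rho",), x0_sd=2.0
        )
        post = invert_subject(obs, u, priors)
        assert np.linalg.norm(post.state_means[-1]) < 0.5
        v_end = map_psychopathology(post.state_means[-1], default_params.nosology)
        d_end = map_diagnosis(v_end, default_params.nosology)
        assert int(np.argmax(d_end)) == 3


class TestParameterRecovery:
    def test_trait_coverage_of_90_percent_intervals(self, default_params):
        """Over 20 simulated subjects with three free dynamical traits, the
        90% posterior intervals cover the generating values at close to the
        nominal rate (one-sided binomial allowance at n = 60 checks)."""
        u = InterventionSeries.none(64)
        free = ("rate_sigma", "rayleigh_rho", "geom_beta")
        hits = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            tv = np.array([10.0, 32.0, 8.0 / 3.0]) + np.array(
                [1.0, 1.0, 0.25]
            ) * rng.standard_normal(3)
            truth = ModelParameters(
                traits=SubjectTraits(
                    rate_sigma=tv[0], rayleigh_rho=tv[1], geom_beta=tv[2]
                )
            )
            _, obs = simulate(truth, u, noise=FluctuationSpec(seed=2000 + seed))
            priors = PriorSpec.for_model(default_params, free=free, x0_sd=2.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                post = invert_subject(obs, u, priors)
            lo, hi = post.parameter_interval90()
            hits.extend(l <= t <= h for l, h, t in zip(lo, hi, tv))
        rate = float(np.mean(hits))
        n = len(hits)
        band = 1.645 * np.sqrt(0.85 * 0.15 / n)
        assert rate >= 0.85 - band, f"coverage {rate:.2f} over {n} intervals"


class TestEvidence:
    @pytest.fixture(scope="class")
    def noisy_obs(self, default_params):
        u = InterventionSeries.none(64)
        _, obs = simulate(default_params, u, noise=FluctuationSpec(seed=21))
        return obs, u

    def test_deterministic_given_seed(self, default_params, noisy_obs):
        obs, u = noisy_obs
        priors = PriorSpec.for_model(
            default_params, free=("rayleigh_rho",), x0_sd=2.0
        )
        p1 = invert_subject(obs, u, priors)
        p2 = invert_subject(obs, u, priors)
        assert log_evidence(p1) == log_evidence(p2)

    def test_trace_final_value_is_the_evidence(self, default_params, noisy_obs):
        obs, u = noisy_obs
        priors = PriorSpec.for_model(
            default_params, free=("rayleigh_rho",), x0_sd=2.0
        )
        post = invert_subject(obs, u, priors)
        assert post.evidence_trace[-1] == log_evidence(post)

    def test_trace_non_decreasing_within_tolerance(self, default_params, noisy_obs):
        obs, u = noisy_obs
        priors = PriorSpec.for_model(
            default_params, free=("rayleigh_rho",), x0_sd=2.0
        )
        post = invert_subject(obs, u, priors)
        drops = np.diff(post.evidence_trace)
        floor = -InversionSettings().convergence_tolerance * np.maximum(
            1.0, np.abs(post.evidence_trace[1:])
        )
        assert np.all(drops >= 2 * floor)

    def test_irrelevant_parameter_cannot_raise_evidence(
        self, default_params, noisy_run
    ):
        """With no intervention the sensitivity parameter is unidentified:
        freeing it cannot improve the evidence, and freeing an identified
        parameter costs complexity that data generated at the prior means
        cannot repay."""
        _, obs, u = noisy_run
        pri_red = PriorSpec.for_model(
            default_params, free=("rayleigh_rho",), x0_sd=1.0,
        )
        pri_irrelevant = PriorSpec.for_model(
            default_params,
            free=("rayleigh_rho", "intervention_sensitivity"),
            x0_sd=1.0,
        )
        pri_identified = PriorSpec.for_model(
            default_params, free=("rayleigh_rho", "geom_beta"), x0_sd=1.0,
        )
        e_red = invert_subject(obs, u, pri_red).evidence
        e_irr = invert_subject(obs, u, pri_irrelevant).evidence
        e_ident = invert_subject(obs, u, pri_identified).evidence
        assert e_red >= e_irr - 1e-3
        assert e_red > e_ident


class TestDiagnosisTransform:
    def test_uniform_maps_to_origin(self):
        assert np.allclose(diagnosis_to_unconstrained(np.full(4, 0.25)), 0.0)

    def test_round_trip_on_random_simplex_points(self):
        rng = np.random.default_rng(1)
        d = rng.dirichlet(np.ones(4), size=50)
        z = diagnosis_to_unconstrained(d)
        back = unconstrained_to_diagnosis(z)
        assert np.max(np.abs(back - d)) < 1e-9

    def test_zero_entries_are_clipped_to_finite_values(self):
        z = diagnosis_to_unconstrained(np.array([1.0, 0.0, 0.0, 0.0]))
        assert np.all(np.isfinite(z))


class TestValidation:
    def test_free_parameter_requires_positive_sd(self):
        with pytest.raises(ValueError):
            ParamPrior(mean=1.0, sd=0.0, free=True)

    def test_mismatched_grids_rejected(self, default_params, untreated_run):
        _, obs, _ = untreated_run
        priors = PriorSpec.for_model(default_params)
        with pytest.raises(ValueError):
            invert_subject(obs, InterventionSeries.none(32), priors)

    def test_non_convergence_warns(self, default_params):
        u = InterventionSeries.none(64)
        _, obs = simulate(default_params, u, noise=FluctuationSpec(seed=4))
        priors = PriorSpec.for_model(
            default_params, free=("rayleigh_rho",), x0_sd=2.0
        )
        settings = InversionSettings(
            max_iterations=2, convergence_tolerance=1e-12, max_restarts=0
        )
        with pytest.warns(RuntimeWarning):
            post = invert_subject(obs, u, priors, settings=settings)
        assert not post.converged
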