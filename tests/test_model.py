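"""Generative-model unit and property tests: flow, observation maps, noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psychodyn import (
    FluctuationSpec,
    InterventionSeries,
    ModelParameters,
    NosologyMap,
    SubjectTraits,
    default_nosology,
    flow,
    map_diagnosis,
    map_psychopathology,
    map_symptoms,
    sample_smooth_noise,
    simulate,
)
from psychodyn.model import IntegrationDivergence, effective_rho

finite_v = st.tuples(
    st.floats(-50, 50, allow_nan=False), st.floats(-50, 50, allow_nan=False)
).map(np.array)


class TestFlow:
    def test_origin_is_fixed_point_for_any_dose(self):
        traits = SubjectTraits()
        for u in (0.0, 0.5, 10.0):
            assert np.allclose(flow(np.zeros(3), u, traits), 0.0)

    def test_hand_evaluated_derivative(self):
        # sigma (x2-x1), x1 (rho - x3) - x2, x1 x2 - beta x3 at (1,1,1)
        traits = SubjectTraits(rate_sigma=10.0, rayleigh_rho=32.0, geom_beta=8.0 / 3.0)
        dx = flow(np.ones(3), 0.0, traits)
        assert np.allclose(dx, [0.0, 30.0, -5.0 / 3.0])

    def test_dose_attenuates_rayleigh_coupling(self):
        traits = SubjectTraits()
        rhos = effective_rho(np.array([0.0, 0.5, 1.0, 2.0]), traits)
        assert rhos[0] == traits.rayleigh_rho
        assert np.all(np.diff(rhos) < 0)

    def test_large_dose_stabilizes_origin(self):
        # with rho_eff < 1 all Jacobian eigenvalues at the origin have
        # negative real part
        traits = SubjectTraits()
        u = 2.0  # rho_eff = 32 e^-8 << 1
        rho_eff = effective_rho(u, traits)
        assert rho_eff < 1
        J = np.array(
            [
                [-traits.rate_sigma, traits.rate_sigma, 0.0],
                [rho_eff, -1.0, 0.0],
                [0.0, 0.0, -traits.geom_beta],
            ]
        )
        assert np.max(np.linalg.eigvals(J).real) < 0

    def test_zero_sensitivity_makes_flow_dose_independent(self):
        traits = SubjectTraits(intervention_sensitivity=0.0)
        x = np.array([3.0, -2.0, 17.0])
        assert np.allclose(flow(x, 0.0, traits), flow(x, 5.0, traits))

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            flow(np.array([np.nan, 0, 0]), 0.0, SubjectTraits())


class TestObservationMaps:
    def test_psychopathology_is_declared_linear_mixture(self):
        nos = default_nosology()
        nos.mixing = np.array([[1.0, 1.0], [1.0, -1.0]])
        v = map_psychopathology(np.array([0.0, 2.0, 3.0]), nos)
        assert np.allclose(v, [5.0, -1.0])
        nos.mixing = np.zeros((2, 2))
        assert np.allclose(map_psychopathology(np.array([1.0, 2.0, 3.0]), nos), 0.0)
        nos.mixing = np.eye(2)
        assert np.allclose(
            map_psychopathology(np.array([9.0, 2.0, 3.0]), nos), [2.0, 3.0]
        )

    def test_symptoms_vanish_at_origin_and_saturate(self):
        nos = default_nosology()
        assert np.allclose(map_symptoms(np.zeros(2), nos), 0.0)
        s = map_symptoms(np.array([1e6, -1e6]), nos)
        assert np.all(np.abs(s) <= 1.0)
        assert np.any(np.abs(s) > 1 - 1e-9)

    @given(v=finite_v)
    @settings(max_examples=50, deadline=None)
    def test_symptoms_bounded_and_diagnosis_on_simplex(self, v):
        nos = default_nosology()
        s = map_symptoms(v, nos)
        assert np.all(np.abs(s) < 1.0)
        d = map_diagnosis(v, nos)
        assert np.all(d >= 0)
        assert abs(d.sum() - 1.0) < 1e-12

    def test_equidistant_point_gives_uniform_diagnosis(self):
        nos = NosologyMap(
            mixing=np.eye(2),
            symptom_loadings=np.zeros((6, 2)),
            symptom_offsets=np.zeros(6),
            diagnostic_locations=np.array(
                [[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]]
            ),
            diagnostic_precision=2.0,
        )
        assert np.allclose(map_diagnosis(np.zeros(2), nos), 0.25)

    def test_high_precision_concentrates_on_nearest_category(self):
        nos = default_nosology()
        nos.diagnostic_precision = 10.0
        d = map_diagnosis(np.zeros(2), nos)  # at the remitted location
        assert d[3] > 0.99


class TestSmoothNoise:
    def test_zero_amplitude_is_exactly_zero(self):
        assert np.all(sample_smooth_noise(32, 3, 0.0) == 0.0)

    def test_reproducible_under_seed(self):
        a = sample_smooth_noise(16, 2, 0.5, rng=42)
        b = sample_smooth_noise(16, 2, 0.5, rng=42)
        assert np.array_equal(a, b)

    def test_autocorrelation_matches_squared_exponential_kernel(self):
        # Monte-Carlo check against exp(-tau^2 / (2 l^2)) at the half-interval
        # grid, pooled over many independent series
        ell = 0.5
        n_rep, T = 4000, 64
        rng = np.random.default_rng(7)
        Z = sample_smooth_noise(T, n_rep, 1.0, correlation_length=ell, rng=rng, dt=0.5)
        for lag_steps, tau in ((1, 0.5), (2, 1.0), (4, 2.0)):
            emp = np.mean(Z[:-lag_steps] * Z[lag_steps:])
            assert emp == pytest.approx(np.exp(-(tau**2) / (2 * ell**2)), abs=0.02)
        assert np.var(Z) == pytest.approx(1.0, rel=0.03)

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError):
            sample_smooth_noise(0, 3, 1.0)
        with pytest.raises(ValueError):
            sample_smooth_noise(8, 3, -1.0)


class TestSimulate:
    def test_deterministic_given_seed(self, default_params):
        u = InterventionSeries.none(64)
        noise = FluctuationSpec(seed=5)
        out1 = simulate(default_params, u, noise=noise)
        out2 = simulate(default_params, u, noise=noise)
        assert np.array_equal(out1[0].x, out2[0].x)
        assert np.array_equal(out1[1].diagnosis, out2[1].diagnosis)

    def test_zero_noise_equals_deterministic_integration(self, default_params):
        from psychodyn.model import integrate_interval

        u = InterventionSeries.none(16)
        latent, _ = simulate(default_params, u)
        x = np.array([8.0, 10.0, 32.0])
        for t in range(15):
            x = integrate_interval(x, 0.0, default_params.traits)
            assert np.allclose(latent.x[t + 1], x, atol=0.0)

    def test_untreated_trajectory_bounded_chaotic_ambiguous(self, untreated_run):
        latent, obs, _ = untreated_run
        norms = np.linalg.norm(latent.x, axis=1)
        assert norms.max() < 100.0
        assert norms.max() > 10.0
        modal = obs.modal_diagnosis()
        assert (np.diff(modal) != 0).sum() >= 2
        # non-periodic: no exact state recurrence
        assert len({tuple(np.round(row, 9)) for row in latent.x}) == latent.x.shape[0]

    def test_intervention_drives_remission(self, treated_run):
        latent, obs, _ = treated_run
        assert np.linalg.norm(latent.x[-1]) < 0.5
        assert obs.modal_diagnosis()[-1] == 3  # "remitted"

    def test_noisy_outputs_respect_constraints(self, noisy_run):
        _, obs, _ = noisy_run
        assert np.all(np.abs(obs.symptoms) < 1.0)
        assert np.allclose(obs.diagnosis.sum(axis=1), 1.0, atol=1e-9)

    def test_divergence_raises_with_time_index(self):
        params = ModelParameters(
            traits=SubjectTraits(rayleigh_rho=32.0, geom_beta=-5.0)
        )
        with pytest.raises(IntegrationDivergence) as err:
            simulate(params, InterventionSeries.none(64), x0=[8.0, 10.0, 32.0])
        assert err.value.time_index >= 1
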