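# psychodyn

Generative dynamic causal modelling of psychiatric illness trajectories:
simulation, Bayesian inversion, nosological hypothesis testing, and
treatment-response forecasting.

## The problem

Psychiatric diagnoses are usually treated as *causes* of symptoms. This
package implements the opposite, generative view: diagnoses and symptom
scores are *consequences* of latent disease processes. A slow
pathophysiological process x(t) ∈ ℝ³ (standing in for mixtures of, e.g.,
neuromodulatory or endocrine variables) drives a two-dimensional
psychopathology v(t); v(t) in turn generates six normalized symptom scores
(five PANSS items and the BDI) and a probabilistic differential diagnosis
over four ICD-10 categories (F20 schizophrenia, F25 schizoaffective
disorder, F32 depressive episode, remitted). Because the model is
generative, it can be *inverted*: given weekly ratings, one can infer the
latent states and subject traits, score competing hypotheses about the
nosological structure by model evidence, and forecast the response to a
planned intervention — the weather-forecasting workflow applied to
psychiatry.

## The model

Pathophysiology follows Lorenz-form dynamics whose state-dependent coupling
(the Rayleigh number ρ) is attenuated by a therapeutic input u(t):

    ẋ₁ = σ (x₂ − x₁)
    ẋ₂ = x₁ (ρ e^{−θ₃ᵖ u} − x₃) − x₂          (ρ_eff < 1 ⇒ remission attractor)
    ẋ₃ = x₁ x₂ − β x₃

    v = θⁿ (x₂, x₃)ᵀ                            2×2 nosological mixing
    sᵢ = tanh(wᵢ·v + bᵢ) ∈ (−1, 1)              symptom scores
    Δ  = softmax(−α ‖v − θᵢᴰ‖)                  diagnosis simplex

with smooth Gaussian fluctuations (squared-exponential kernel, correlation
length half an assessment interval) entering at the pathophysiology,
psychopathology, and outcome levels. At the default ρ = 32 the untreated
trajectory is chaotic — diagnosis alternates between F20 and F25 — while a
sufficient dose collapses the attractor to the origin, where the "remitted"
category sits.

Inversion is dual state/parameter estimation by variational Laplace:
Gauss–Newton on the discretized trajectory and free parameters, analytic
noise-precision updates with the variational trace correction, and a free
energy (evidence bound) for model comparison. In the linear-Gaussian
special case the scheme reproduces the Kalman/RTS smoother exactly. Group
studies fuse subject posteriors over the shared nosological couplings
(empirical Bayes, fixed effects) with subject traits as random effects, and
the 2⁴ = 16 hypotheses about which couplings exist are scored analytically
by Bayesian model reduction. Forecasts sample the joint posterior over the
current state and traits and integrate the generative model forward.

## Worked example

```python
import numpy as np
from psychodyn import (
    ModelParameters, InterventionSeries, FluctuationSpec, PriorSpec,
    simulate, invert_subject, dose_response, DIAGNOSIS_NAMES,
)

params = ModelParameters()                       # default subject + nosology
u = InterventionSeries.step(64, 32, dose=1.0)    # antipsychotic from week 32
latent, obs = simulate(params, u, noise=FluctuationSpec(seed=1))
print([DIAGNOSIS_NAMES[k] for k in obs.modal_diagnosis()[28:36]])

obs32 = type(obs)(symptoms=obs.symptoms[:32], diagnosis=obs.diagnosis[:32])
priors = PriorSpec.for_model(params, free=("rayleigh_rho",), x0_sd=2.0)
post = invert_subject(obs32, InterventionSeries.none(32), priors)
lo, hi = post.parameter_interval90()
print("rho: %.2f [%.2f, %.2f]" % (post.parameter_mean[0], lo[0], hi[0]))

curve = dose_response(post, np.linspace(0, 2, 8), start_assessment=16,
                      horizon_assessment=48, n_samples=256, seed=1)
print(np.round(curve.remission_probability, 2))
```

prints

```
['F25', 'F20', 'F25', 'F20', 'F20', 'remitted', 'remitted', 'remitted']
rho: 32.01 [31.99, 32.03]
[0.17 1.   1.   1.   1.   1.   1.   1.  ]
```

The intervention at week 32 converts the alternating F20/F25 picture into
sustained remission. The Rayleigh trait is recovered from the first 32
(pre-treatment) weeks alone, and the predicted dose–response curve — built
purely from that pre-treatment posterior — shows a small probability of
spontaneous remission at dose 0 and near-certain remission once the dose is
large enough to destroy the chaotic attractor.

A command-line interface wraps the same pipelines:

```
psychodyn fixture index_patient --out demo --seed 1
psychodyn invert --data demo/timeseries.csv --priors demo/priors.json --out post.json
psychodyn dose-response --posterior post.json --doses 0:2:8 --start 16 --horizon 48 --out curve.csv
```

Subcommands: `simulate | invert | group | reduce | predict | dose-response
| fixture`.

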