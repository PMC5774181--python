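# Methods

This note documents the generative model, the inversion scheme, the group
machinery and the forecasting procedure as implemented, together with the
numerical choices and their rationale. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Generative model

**States and flow.** The latent pathophysiology x ∈ ℝ³ follows Lorenz-form
dynamics with subject traits θᵖ = (σ, ρ, β, θ₃ᵖ): σ is the relaxation rate
of x₁ toward x₂, ρ the Rayleigh number controlling the state-dependent
x₁→x₂ coupling, β the dissipation of x₃, and θ₃ᵖ ≥ 0 the sensitivity to
the therapeutic input. The input acts multiplicatively on the Rayleigh
coupling, ρ_eff(u) = ρ·exp(−θ₃ᵖ u): smooth, equal to ρ at u = 0, and
driving ρ_eff below 1 at large doses so the chaotic attractor is replaced
by a point attractor at the origin. Defaults are the classic chaotic rates
σ = 10, β = 8/3, ρ = 32, with θ₃ᵖ = 4 so that a unit dose yields
ρ_eff ≈ 0.59 < 1.

**Time scale.** One weekly assessment spans `time_scale` = 0.5 dynamical
units. This value is a compromise identified during design: the untreated
default run must alternate its modal diagnosis repeatedly over 64 weeks
(it shows ~20 alternations at 0.5), while inversion must remain tractable —
at markedly smaller time scales the first state decouples from the data
(its relaxation happens within a fraction of an interval) and at larger
ones the per-interval map becomes too chaotic for local optimization.
Integration uses fixed-step RK4 with 16 sub-steps per interval, with an
overflow guard of 10⁶ that raises a divergence error naming the interval.

**Observation model.** Psychopathology is a linear mixture
v = θⁿ(x₂,x₃)ᵀ; the default mixing [[0, 0.1], [0.125, 0.05]] has the
x₂→v₁ coupling exactly zero — the null coupling that the group-level
analyses recover and that model reduction prunes. Symptoms are
s = tanh(Wv + b) with the 6×2 loadings W a unit-Gaussian draw frozen under
a fixed seed (chosen so that no channel saturates beyond float precision
along the default trajectory) and offsets b = 0; scores are clipped to
±(1 − 10⁻¹²) so the open-interval invariant survives float rounding. The
diagnosis is a softmax (inverse temperature α = 1) of the negative
unsquared Euclidean distance from v to the four category locations;
"remitted" sits at the origin (forced by the treated attractor), F20 at
(3, −1) and F25 at (3, 3.5) flank the band the untreated trajectory sweeps
(v₂ flips sign with the Lorenz lobe switches, alternating the diagnosis),
and F32 at (5, 1) is visited rarely.

**Fluctuations.** All fluctuation processes are stationary Gaussians with
squared-exponential autocorrelation exp(−τ²/(2ℓ²)), ℓ = 0.5 assessment
intervals, built by dense Cholesky factorization of the kernel matrix
(series are at most a few hundred points; 10⁻⁸ diagonal jitter). The
pathophysiology-level fluctuation (sd 0.1) enters the equations of motion
as a drift held constant within each interval; the psychopathology-level
fluctuation (sd 0.01) adds to v; the outcome-level fluctuation (sd 0.01)
adds to the pre-sigmoid symptom predictor and the pre-softmax diagnostic
potential. Placing the outcome noise before the output nonlinearities is a
design choice: it keeps symptom scores strictly in (−1,1) and diagnoses
exactly on the simplex, and it makes the transformed-space likelihood used
by the inverter exactly the generative model. The default amplitudes
realize the "very low noise" regime in which latent trajectories remain
visually recoverable from the outcomes.

## Inversion (dual estimation)

**Transformed observations.** Symptoms map through atanh (clipped at
1 − 10⁻¹²) and diagnoses through the log-ratio transform with reference
category "remitted" (probabilities clipped at 10⁻⁶), giving a
9-dimensional unconstrained observation per assessment in which the
generative observation model is additive-Gaussian by construction.

**Objective.** The scheme maximizes a Laplace free-energy bound jointly
over the discretized state trajectory (T×3) and the free parameters, with
Gaussian priors on the initial state and parameters. The negative log
joint is a weighted least-squares functional; Gauss–Newton steps with
Levenberg-style damping (step rejected unless it lowers the objective) are
taken until the relative change of the bound is below 10⁻⁴ on two
successive iterations (max 64). The bound adds ½log|2πΣ| from the GN
Hessian over all states and parameters, plus mean-field terms for the
noise log-precisions. In the linear-Gaussian case the objective is exactly
quadratic, so states, covariances and the bound equal the Kalman/RTS
smoother and the exact marginal likelihood (verified to 10⁻³ in the
tests).

**Noise model.** Two log-precision hyperparameters are estimated with
Gaussian priors (mean at the generating amplitude, sd 1, clipped to ±5
prior sd): one for the dynamical (process) block and one for the outcome
block. Because the generative outcome- and psychopathology-level
amplitudes are tied (equal by default), the 9 outcome channels form a
single block whose per-time covariance structure is exact:
blockdiag(I₆, I₃+11') + MₜMₜᵀ, where Mₜ stacks the symptom loadings and
the diagnostic-potential gradients at vₜ. The process residual
w_t = x_{t+1} − F(x_t) is whitened by its state-dependent gain
G_t = ∂x_{t+1}/∂drift (the integrated within-interval sensitivity,
computed by differencing the integrator) and across time by the
fluctuation kernel. These structures matter: treating the residuals as
iid white produces confidently biased trait estimates, because the
smooth, state-amplified fluctuations carry far less information than an
iid model implies. Precision updates are one-dimensional Newton steps on
the expected sums of squares including the variational trace correction
tr(J_b Σ J_bᵀ) — without the trace term, precision estimation collapses
onto over-fitted deterministic shadow trajectories.

**Initialization.** Chaotic flows defeat the textbook initialization
(forward integration from the prior mean): the initial trajectory diverges
from the data-generating one within a few intervals and Gauss–Newton then
converges to a shadow trajectory with biased parameters. The package
instead initializes from the data: v from the (linear, known) symptom map
by least squares, (x₂,x₃) from v through the mixing, and the unobserved x₁
by a Viterbi-style dynamic program over an x₁ grid whose pairwise costs
are one-interval transition misfits (coarse pass, then a refined pass on a
denser grid around the coarse path). When nosological couplings are free,
the mixing used for this inversion is itself initialized from the data: a
moment-based estimate (the mean of v identifies the x₃ column because x₃
has a large positive mean on the attractor; the residual covariance
identifies the x₂ column, sign-anchored to the prior initial state) is
refined by Nelder–Mead on the scale-normalized dynamic-programming cost —
the dynamics, not the moments, identify the mixing. A free Rayleigh trait
is located the same way by a one-dimensional scan. The reference attractor
moments used for scaling (std x₂ ≈ 10, mean x₃ ≈ 27.6, std x₃ ≈ 9.1) are
properties of the canonical ρ = 32 regime.

**Graduated optimization and restarts.** The dynamical precision is
annealed in (offsets −8, −5, −3, −1.5, 0 on the log precision) so the
strongly nonlinear transition constraint is imposed only once the states
already explain the observations, followed by two cyclic re-annealings
that escape shallow local optima. If the result fails dynamical sanity
checks (non-convergence, process precision at the floor of its prior
range, or a free parameter more than 4 prior sd from its mean), the solver
retries: first a slower annealing schedule with parameters frozen during
the stages, then jittered re-initializations, keeping the best
non-degenerate solution. Fits that still fail are returned flagged
`converged=False` with a warning — at the cohort study conditions this
affects roughly one subject in eight — and the group machinery excludes
them (with a warning) as quality control.

**Known limitations.** The posterior remains mildly overconfident:
measured 90%-interval coverage for three free traits over seeded
replicates is ~0.83–0.85 rather than 0.90, consistent with the local
(Laplace) approximation on a chaotic likelihood surface. There is also an
exact symmetry of the flow, (x₁,x₂) → (−x₁,−x₂) with the x₂ mixing column
negated; it is broken by the prior on the initial state and by the
sign-anchoring of the initialization, but fits started on the wrong side
of it are among those caught by the sanity checks.

## Group analysis and model reduction

Nosological couplings are fixed effects: the group posterior multiplies
each converged subject's Gaussian likelihood update (posterior precision
minus prior precision, in natural parameters) under the common prior. A
single-subject "group" therefore reproduces that subject's posterior
exactly. Subject traits are random effects: each subject keeps its own
posterior, and a population mean and between-subject sd per trait are
estimated by maximizing the marginal likelihood of the posterior means
over a log-precision grid with a weakly-informative N(0,1) prior on the
log between-subject precision. The group evidence accumulates the subject
bounds with the Gaussian fusion correction.

For cohort inversions the mixing prior is centred on a generic,
well-conditioned reference ([[0.06, 0.12], [0.10, 0.03]], sd 0.25 per
entry) deliberately different from the generating nosology, so that
recovery is demonstrably data-driven; the Rayleigh trait is free per
subject (prior N(32, 2²)).

The 16 hypotheses about which of the four couplings exist are indexed
canonically (bit i of index−1 = inclusion of the i-th coupling in the
order x₂→v₁, x₃→v₁, x₂→v₂, x₃→v₂). Excluding a coupling means replacing
its prior by N(0, 10⁻⁸) — a numerically stable stand-in for a delta prior —
and the evidence change and reduced posterior follow analytically from
the full prior/posterior pair (verified against the conjugate-regression
closed form to 10⁻⁶). The analytic reduction is quantitatively accurate
in the full posterior's quadratic neighborhood (identity reduction and
null-coupling exclusion agree with direct re-inversion to well under half
a nat); for strongly misspecified reductions it overstates the evidence
loss relative to a re-fit, while agreeing on the decisive rejection — the
acceptance surface for model selection is therefore the winning inclusion
mask, not the magnitude of a rejected model's evidence.

## Forecasting

Forecasts sample n (default 512) draws from the joint Gaussian posterior
over the final state and free parameters, integrate the generative
dynamics forward under the hypothetical intervention with smooth process
fluctuations at the inferred precision, and push each trajectory through
the observation model with outcome fluctuations. Summaries are pointwise
means and central 90% bands; the remission probability at a horizon is the
Monte-Carlo frequency with which "remitted" is the arg-max diagnosis
there. The dose–response scan repeats this over a dose grid with a step
intervention. Forecast band calibration (realized future states inside the
90% band) is checked empirically in the acceptance suite. With the
default parameterization the predicted dose–response rises steeply: once
the dose pushes ρ_eff below the chaotic regime the fixed points sit close
enough to the origin to be classified remitted, so the curve saturates
near 1 rather than plateauing midway — the shape, not the plateau value,
is the modelled quantity.

## Study sizes in the validation suite

The packaged checks use: 64 weekly assessments per subject; 8-subject
cohorts with ρᵢ ~ N(32, 1); 10 replicate cohorts for the model-selection
winner rate; 20 seeded subjects for trait-recovery coverage and forecast
calibration (the acceptance script uses 12 and 4 replicates for the
calibration and winner-rate summaries respectively); 10⁴ series for the
fluctuation-kernel check. These sizes give stable Monte-Carlo summaries
while keeping a full validation run within minutes on a single CPU.

## What the simulations do and do not show

All validation data are generated by the package's own simulator, so
passing tests demonstrate internal consistency — that the inversion,
model-comparison and forecasting machinery recover what the generative
model planted, at realistic noise levels and with deliberately
non-informative initializations for the quantities under study. They do
not demonstrate that real clinical ratings follow Lorenz-form dynamics,
that real diagnosis probabilities are softmax in a two-dimensional
construct space, or that real assessment noise is as small or as smooth
as the defaults; the latent states are explicitly mixtures with no claim
of physiological identity.
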