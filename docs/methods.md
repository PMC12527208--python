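# Methods

`headingci` implements a family of Bayesian observer models of heading
estimation in a moving environment, together with the synthetic experiment,
stimulus mathematics, fitting machinery and behavioral analyses needed to
study them end to end. This note documents the model, the numerical
choices, and what the synthetic experiments do and do not establish.

## The generative model

A trial has three latent lateral velocities (deg/s): the observer's
self-motion `s_self`, and the environmental motion before (`s_env0`) and
during (`s_env`) self-motion. A binary causal structure `C` states whether
the environmental motion remained constant across the two epochs (`C=1`:
`s_env = s_env0`) or changed (`C=2`: independent draws). Priors are
zero-mean Gaussians — the "slow-speed prior": `s_self ~ N(0, σ_self²)`,
`s_env0, s_env ~ N(0, σ_env²)`, and `P(C=1) = p_constant`.

The senses deliver three conditionally independent Gaussian measurements:

    x_vest ~ N(s_self,          σ_vest²)        vestibular
    x_vis  ~ N(s_self − s_env,  σ_vis²)         retinal motion during
    x_vis0 ~ N(−s_env0,         σ_vis0²)        retinal motion before

Visual noise obeys Weber's law, `σ_vis = w_vis·|s_self − s_env|` and
`σ_vis0 = w_vis·|s_env0|`. Because Weber-law variance vanishes exactly when
the generating signal is zero (pre-motion epoch of the Acceleration
condition; nulled retinal motion), both visual SDs are floored at a
configurable `noise_floor` (default 1e-3 deg/s). The floor keeps every
measurement density proper for sampling and kernel density estimation while
perturbing predictions negligibly (it is ~3 orders of magnitude below the
smallest nonzero Weber SD in the design).

The model observer's assumed likelihood widths equal the generative widths:
one parameterization serves both simulation and inference.

### Units: heading angle vs lateral velocity

The vestibular cue is an angle-of-motion percept while the visual cues are
image velocities; the estimators combine them on one axis, so a common
scale is mandatory. All latent signals live on a lateral-velocity axis in
deg/s; heading angle θ (deg from vertically upward, positive rightward)
maps through `lateral = v_ref · sin(θ)` with `v_ref = 8.5` deg/s, the peak
platform velocity, so that a 90° (fully lateral) heading at peak speed has
lateral velocity commensurate with the visual velocity range. The inverse
mapping clamps its argument, so estimates whose magnitude exceeds `v_ref`
report ±90°. `v_ref` is configurable everywhere (`reference_speed`), and
because the mapping is monotone the qualitative model behavior is
insensitive to its exact value.

## Observer models

All Bayesian models share one closed form: given an effective visual cue
with mean `μ_K` and variance `σ_K²`, the per-structure estimate is the
precision-weighted mean of the vestibular cue, the visual cue, and the
zero-centered prior,

    ŝ_C = (x_vest/σ_vest² + μ_K/σ_K²) / (1/σ_vest² + 1/σ_K² + 1/σ_self²).

Under `C=1` the pre-motion signal is used to infer and subtract the
environmental motion (`μ_K = x_vis − σ_env²/(σ_env²+σ_vis0²)·x_vis0`);
under `C=2` it is discarded and the prior stands in for the unknown
environmental motion (`μ_K = x_vis`, `σ_K² = σ_vis² + σ_env²`). The
structure posterior uses the analytic Gaussian marginal of the cues given
`C` (a factor `K0`, common to both structures, cancels and is omitted).
The eight models then differ only in how the two structure estimates are
combined or replaced:

| model | rule | free parameters (k) |
|---|---|---|
| `cci` | posterior-weighted average over C | σ_self, σ_env, σ_vest, w_vis, p_constant (5) |
| `integration` | always C=1 | 4 |
| `segregation` | always C=2 | 4 |
| `covariance` | bivariate prior on (s_env0, s_env), correlation ρ | 5 |
| `fixed` | α_vest·x_vest + α_mom·x_vis + α_cont·(x_vis − x_vis0) | σ_vest, w_vis, 3 α (5) |
| `heuristic` | structure chosen by cue-conflict comparison, no uncertainty | 4 |
| `wta` | commit to a-posteriori likelier structure | 5 |
| `mci` | momentary causal inference on (x_vest, x_vis) only | σ_self, σ_vest, w_vis, p_common (4) |

Notes on individual models:

* **Covariance** interpolates exactly between the two structures: ρ=1
  reproduces `integration` and ρ=0 reproduces `segregation` (asserted in
  tests). ρ is bounded to [0, 1]; negative temporal correlation of
  environmental motion has no motivation here.
* **Heuristic** compares `|x_vest − μ_K,C=1|` against `|x_vest − μ_K,C=2|`
  and takes the C=1 estimate when its conflict is *greater or equal*. That
  inequality direction is the model's defining piecewise rule and is
  implemented verbatim (ties to C=1); an `as_printed=False` flag inverts
  it for sensitivity analysis, since the direction is counterintuitive and
  model comparison on data is what disambiguates the two readings.
* **MCI** uses a single σ_self for both of its latent sources. Its
  internal visual-noise assumption σ_vis = w_vis·|source| coincides with
  the generative width because its latent visual source corresponds to the
  retinal motion `s_self − s_env`.
* **Tie-breaking** in `heuristic` and `wta` sends exact ties to the C=1
  branch.

All likelihood/posterior arithmetic runs in log space with stable
two-term softmax; estimators are vectorized over trial batches and
dtype-preserving (the fitting hot path runs them in single precision,
which is ~7 significant digits — orders of magnitude finer than any
behavioral quantity involved).

A brute-force oracle (`numeric_posterior_mean`) computes the posterior
mean of `s_self` by dense trapezoid quadrature over the full latent space
(2-D grids for the contextual models, 3-D for the covariance model, capped
at 201 points/axis to bound memory). Trapezoid sums over ±9 SD windows are
spectrally accurate for Gaussian integrands; the oracle shares no code
with the closed forms and anchors the correctness tests.

## Synthetic experiment

`build_design` crosses 5 visual velocities (0, ±5, ±10 deg/s) × 10 headings
(±5°…±45°) × 3 conditions × `reps` (default 5) = 750 trials / 150 distinct
conditions, with the pre-motion environmental velocity set by the condition
(Acceleration: 0; Constant: `s_env`; Deceleration: `2·s_env`). Trial order
is uniformly randomized: the conditions were randomly interleaved in the
task, and the session's block structure has no bearing on trial-independent
observer models.

`simulate_observer` draws measurements, applies a model estimator, and
maps the lateral estimate to a reported heading (clamped at ±90°, since
estimates can exceed `v_ref` in magnitude). Latent measurements and
per-trial diagnostics (structure posterior, per-structure estimates) are
retained in simulation mode.

Cohort samplers define the conditions of the recovery experiments, chosen
once as plausible for the stimulus range (velocities ≤ 10 deg/s, lateral
self-motion ≤ 8.5 deg/s):

* `sample_cci_params`: σ_self, σ_env ≈ 5·e^{N(0,0.25)}, σ_vest ≈
  2·e^{N(0,0.4)}, w_vis ≈ 0.15·e^{N(0,0.3)}, p_constant ~ U(0.2, 0.8).
* `sample_fixed_params`: the same noise scales with weights α_vest ~
  U(0.4, 0.8), α_mom, α_cont ~ U(0.1, 0.35) — a linear-integration null.

The *representative* contextual observer used for qualitative bias
diagnostics is (σ_self, σ_env, σ_vest, w_vis, p_constant) = (5, 5, 2.5,
0.2, 0.3). The behavioral data show heading biases opposite to the visual
motion in every condition — compensation is incomplete even when the
environment is constant — and that regime corresponds to p_constant below
roughly 0.35 at moderate visual reliability. A scan over p_constant
0.2–0.5 × w_vis 0.15–0.25 × σ_vest 2–3 shows the all-negative, speed-
monotone, condition-ordered bias pattern holds over a broad contiguous
region; the chosen point is its center. The condition ordering
|Acceleration| > |Constant| > |Deceleration| at 10 deg/s held at every
scanned point, so it is a structural property of the model, not of the
particular parameter choice.

What the synthetic data deliberately do **not** emulate: report/motor
noise (the marginalization covers sensory noise only), inter-trial
adaptation or session effects, lapses, and any asymmetry between leftward
and rightward motion. Passing recovery tests therefore show that the
fitting machinery is consistent for data generated by the models
themselves — they bound identifiability and estimator quality, not the
models' adequacy for real observers.

## Stimulus mathematics

* **Velocity profiles**: raised-cosine rise, plateau, raised-cosine fall;
  defaults 8.5 deg/s peak held 0.4 s within a 2 s total at 60 Hz.
  Condition schedules hold the pre-motion velocity for 2 s and, for
  Acceleration/Deceleration, ramp to the desired velocity at inertial
  onset, hold 0.4 s, and return to the initial velocity over 0.8 s.
* **Motion clouds**: white noise bandpass-filtered in the 3-D Fourier
  domain by the product of (a) a Gaussian speed-plane term
  `exp(−½((f_x·V_x + f_y·V_y + f_t)/(B_v·f_r))²)` concentrating energy on
  the plane of rigid translation with width proportional to `B_v·f_r`
  (the standard motion-cloud construction; the placement of `B_v` in the
  denominator is the reading consistent with a speed bandwidth in deg/s),
  and (b) a log-scale radial term
  `(1/f_r)·exp(−½(ln(f_r/sf₀)/ln((sf₀+B_sf)/sf₀))²)`. Defaults: V=10
  deg/s, B_v=2.1 deg/s, sf₀=B_sf=0.5 cpd, 128² px covering a 25°-radius
  field at 60 Hz. The random phase spectrum comes from Fourier-transformed
  white noise, which is Hermitian by construction; Nyquist planes are
  zeroed (their frequency sign is ambiguous and would break the symmetry),
  and the spatial DC is excluded (1/f_r is undefined), leaving the mean at
  mid-gray after normalization to [0, 1].
* **Diagnostics**: the dominant velocity is recovered by an
  energy-weighted least-squares plane fit to the 3-D spectrum; the
  spatial-frequency profile is read as energy per logarithmic frequency
  bin after dividing out the `∝ f_r` temporal bandwidth of the speed
  plane, on which scale the envelope peaks at sf₀ by construction.

## Fitting

The estimators map measurements to estimates deterministically, but the
measurements are hidden, so the response likelihood marginalizes over
them: per stimulus condition, `n_mc` (default 1000) measurement triples
are drawn, pushed through the estimator, and a Gaussian KDE of the
simulated estimates is evaluated at the observed responses (on the lateral
scale). Numerical choices:

* **Bandwidth**: Silverman's rule, `0.9·min(SD, IQR/1.349)·n^{−1/5}` per
  condition, floored at 1e-3 deg/s — the floor doubles as the narrow-kernel
  fallback when all simulated estimates coincide (e.g. zero-velocity
  conditions at tiny w_vis).
* **Density floor**: 1e-9, keeping the objective finite for responses far
  outside the simulated support.
* **Priors** (MAP): independent log-normals on σ_self, σ_env, σ_vest
  (log-mean 1) and w_vis (log-mean −2), all log-SD 1 (≈95% of mass within
  a factor 7 of the median); flat priors on the naturally bounded
  parameters (probabilities, ρ, the weights).
* **Bounds**: σ ∈ [1e-3, 50] deg/s, w_vis ∈ [1e-3, 2], probabilities and
  ρ ∈ [0, 1], fixed-model α ∈ [−2, 2] (sign unconstrained), diagnostic
  α_1, α_2 ∈ [0, 1] (weights on a convex combination).
* **Optimizer**: the Monte-Carlo objective is stochastic, so the search
  uses common random numbers — one frozen set of standard-normal draws per
  fit — making the surface deterministic and smooth enough for bounded
  Powell over transformed coordinates (log scale for the positive
  parameters). Restarts (default 5) start from Latin-hypercube points
  inside an initialization window centered on the priors; `xtol` 1e-3 in
  transformed coordinates (≈0.1% parameter resolution, far below recovery
  precision), at most 1000 evaluations per restart, best restart kept.
* **Reporting**: the final log likelihood averages 100 fresh objective
  evaluations at the optimum (independent Monte-Carlo draws) with the log
  prior subtracted; `AIC = 2k − 2·logL`. `model_r2` compares per-condition
  mean predictions from 10,000 simulated estimates per condition with
  per-condition mean observed reports, in degrees.

Model comparison reports per-observer AIC differences against a reference
model with a percentile bootstrap CI over observers (default 2000
resamples).

Problem sizes for the recovery experiments (both in the test suite and in
`scripts/acceptance.py`): 14 observers × 750 trials, `n_mc` 500 with 3
restarts for the observer-model fits, and 2 restarts for the six-parameter
adaptive-weight fits — sizes at which parameter recovery is stable while a
full cohort (56 model fits + 28 diagnostic fits) completes in minutes.

## Behavioral analyses

* **Heading bias**: per-trial angular error (reported − true heading),
  sign-flipped on leftward-visual trials so positive bias points along the
  visual motion, aggregated by condition × unsigned speed. 0 deg/s trials
  enter unflipped — symmetric in expectation, and exactly mirror-antisymmetric
  in any finite sample, which the tests assert separately from the
  nonzero-speed mirror invariance. Empty cells are reported missing, never
  zero.
* **Cue regression**: per-observer OLS of the lateral estimate on the
  three cue predictions — vestibular `s_self`, momentary `s_self − s_env`,
  contextual `s_self − s_env + s_env0` — plus intercept, on signed
  quantities (no mirroring; the predictors are odd in the stimulus). A
  rank-deficient design (e.g. a single condition, which collapses the
  contextual predictor onto another) raises instead of silently
  pseudo-inverting. Group-level one-sample t statistics are provided.
* **Adaptive weights**: the diagnostic replaces the structure posterior
  with one of two free weights on the C=1 estimate chosen by the *true*
  causal state (`α_1` when `s_env0 = s_env`, which literally includes all
  0 deg/s trials, `α_2` otherwise) and fits {σ_self, σ_env, σ_vest, w_vis,
  α_1, α_2} with the same MC/KDE machinery. A causal-inference observer
  yields α_1 > α_2; any fixed-weight integrator yields α_1 ≈ α_2. This is
  an analysis of behavior, not an observer model: it conditions on latent
  state the observer cannot access.

## Known limitations

* The angle↔velocity commensuration is a modeling choice the behavioral
  paradigm does not pin down; all conclusions from simulations are
  conditional on it (an alternative mapping only rescales the lateral
  axis).
* KDE-based likelihoods are biased at the distribution tails (density
  floor) and near hard clamps of the report mapping; with moderate
  parameters clamped reports are rare.
* The Powell/CRN search is a deterministic surrogate for a noise-aware
  Bayesian optimizer; with the default restarts it is robust on these
  5–6 dimensional problems but offers no global guarantee.
* Bootstrap CIs over 14 observers are percentile CIs at small n; their
  coverage is validated at ~90% rather than the nominal 95%.
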