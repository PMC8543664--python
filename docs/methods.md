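# Methods notes

This note records the models, algorithms and design decisions behind
`normtrade`, in the spirit of a package vignette: what is computed, under
which assumptions, and where the genuinely open choices were made.

## Distribution families

**Skew Student t (SST).** A Fernandez–Steel skewed t variable X with
skew factor ν > 0 and τ > 2 degrees of freedom has density
c·t_τ(xν) for x < 0 and c·t_τ(x/ν) for x ≥ 0, c = 2/(ν + 1/ν).
Its mean m and SD s exist in closed form for τ > 2, and the SST variate
is Y = μ + σ(X − m)/s, so that **μ is the mean and σ the standard
deviation** of the conditional score distribution — the property that
makes normal and homoscedastic variants of a population model exact
restrictions rather than approximations. ν = 1 gives symmetry (ν < 1
skews left), and the family converges to N(μ, σ²) as τ → ∞. Density,
cdf and quantile are closed-form (via the Student t cdf/quantile), and
are validated in the tests against adaptive-quadrature and
moment-integration oracles rather than against a transcribed formula.

**Box–Cox Power Exponential (BCPE).** z = ((y/μ)^ν − 1)/(σν) (log form
at ν = 0) is modelled as a standardized power-exponential variable with
kurtosis power τ (τ = 2 normal), with the exact truncation normalizer
P(|T| < 1/(σ|ν|)) for the positive support. μ is approximately the
median and σ approximately the coefficient of variation. Because
simulated test scores can be negative, BCPE models are fitted on
scores + 100 and every quantile/cdf evaluation back-shifts — the offset
is carried inside `ModelSpec` so downstream code never sees shifted
scores.

**Normal.** The ν = 1, τ = ∞ limit is implemented as the exact Gaussian
family rather than an SST with a huge τ: estimating τ near its boundary
is exactly the kind of instability the normal variants are meant to
exclude from the data-generating truth.

Sampling for every family is inverse-cdf applied to uniform draws from
a `numpy` Generator, so a sample is reproducible from its seed alone.

## Age bases

Orthogonal polynomials are orthonormalized against the sample age
vector by QR decomposition; the triangular transform is stored so a
fitted curve can be evaluated at arbitrary ages. P-splines are cubic
B-splines on **6 interior knots, equally spaced and extended uniformly
beyond the age range** (Eilers–Marx construction), with a second-order
difference penalty on adjacent coefficients. On the uniform extended
grid the penalty null space corresponds exactly to straight lines, so
the infinite-smoothing limit of a penalized fit is the least-squares
line — a property the tests exercise directly. Whether "6 knots" should
count interior knots, total knots or basis dimension is a convention
choice; interior knots was adopted and is configurable (`TermSpec.n_knots`).
Evaluation outside the training range (only relevant for edge rounding,
since the evaluation grid equals the sampling range) continues the
spline linearly with its boundary slope.

## Fitting algorithm

`NormingModel.fit()` maximizes the penalized log-likelihood by
backfitting across the distributional parameters (the RS-type strategy
of the GAMLSS literature): for each parameter in turn, the
per-observation score u = ∂ℓ/∂η and curvature w = −∂²ℓ/∂η² with respect
to that parameter's link-scale predictor η are obtained by central
numerical differentiation of the exact log-likelihood (step 1e-5), and
the coefficients are updated by one penalized weighted least-squares
step on the working response z = η + u/w. Non-positive or non-finite
curvatures fall back to a quasi-Fisher u² weight. Each step is accepted
only if it does not increase the penalized deviance (with step-halving
otherwise), cycling continues until the change in global deviance falls
below the tolerance (default 1e-3, mirroring common practice), and one
extra "polish" cycle with frozen smoothing parameters is run after the
criterion triggers — Newton convergence is quadratic near the optimum,
so the polish cycle buys several digits for closed-form comparisons at
negligible cost. Hitting the iteration cap (default 2000) returns
usable coefficients flagged `converged=False` (counted as type-2
nonconvergence and *included* in all outcome computations); numerical
failure returns a `failed` result with no coefficients (type-1,
excluded). Monotonicity of the penalized likelihood from initialization
to return is verified at the final smoothing parameters and a violation
is treated as a failure.

Link-scale predictors are clipped to generous family-valid ranges
(e.g., ln(τ−2) ∈ [−12, 12]) before inversion, which keeps intermediate
likelihood evaluations finite without affecting interior optima.

**Smoothing selection.** A P-spline term with `lam="auto"` has its λ
chosen inside each backfitting update by golden-section search on the
local GAIC of the working penalized regression, weighted RSS + k·edf,
with k from `ModelSpec.gaic_penalty` (5 in the study; ln n gives
BIC-type selection; 0.1 the deliberately overflexible variant). The
search interval is scaled by tr(XᵀWX)/tr(P) so selection is invariant
to the magnitude of the working weights; on a flat criterion the
smoother end wins. `select_lambda` additionally offers an explicit
outer profile search (fit per candidate λ, score by global GAIC) whose
optimum is verified in the tests to beat the grid endpoints.

**Initialization.** μ coefficients from a (lightly ridged) least-squares
fit of the scores on the μ design; σ constant at the residual SD; ν and
τ at family defaults (SST: ν = 1, τ = 3; BCPE: ν = 1, τ = 2).

Effective df of a penalized term is tr[(XᵀWX + λP)⁻¹XᵀWX] at the final
weights; unpenalized terms count their columns.

## Population models

The data-generating truth is an SST whose parameters follow polynomials
of the scaled age u = (age − 13)/8 on the link scale: degree 4 for μ,
2 for ln σ, 4 for ln ν, 1 for ln(τ − 2). The anchoring empirical
model's coefficients were never published, so the shipped default is an
explicit "IDS-like" choice with the qualitative features of
developmental-test norms: the mean rises steeply in childhood
(μ ≈ 7 → 30 raw-score points over ages 5–21) and decelerates; σ varies
mildly with age (≈ 4.5–5.5); the distribution is left-skewed
(ν ≈ 0.6–0.9); tails are moderately heavy (τ ≈ 5–8). All acceptance
checks are defined relative to the active configuration, which is fully
overridable (`PopulationModel(curves=...)`).

Restricted variants replace the μ curve by its least-squares line over
the age range (linear), the σ curve by its age-average (homoscedastic),
and the family by the exact normal (normal) — the three restriction
flags generate the 2³ = 8 factorial populations. Ages in a normative
sample are deterministic (n evenly spaced values on [5, 21]); only
scores are random.

## Study design

Estimation models are defined relative to the population (see
`study.build_estimation_spec`). One genuinely open choice: the source
design specifies the True model's μ term (linear for linear
populations, P-splines otherwise) but not the σ/ν/τ terms; here they
**mirror the population's constancy structure** — intercepts for
constant parameters, P-splines for age-varying ones — on the reasoning
that the "true" model should match the truth parameter by parameter.
Likewise Flex[trans] frees σ, ν, τ as P-splines while leaving the
longitudinal μ term at the population's structure, and BCPE uses
P-splines for all four parameters.

Applicability follows the restriction logic: a Strict variant applies
only when the population has the structure being removed, a Flex
variant only when the population lacks the structure being added, and
combined variants need both; True[poly] applies only to the fully
flexible population. This yields 43 population × estimation
combinations and 129 conditions across n ∈ {500, 1000, 2000}.

One sample per (population, n, replicate) is generated — child seeds
derive from the master seed by a counter-based `SeedSequence`, all
below 2³¹ — and is shared by every applicable estimation model, so
between-model contrasts are computed under common random numbers.
Replicates are independent work units and the reduction order is fixed
by replicate index, so results are scheduling-independent.

Outcomes are accumulated on an I × J grid (ages × population z values
in [−3, 3]; the full design uses I = 1000, J = 100) with estimated z
clamped to [−5, 5] after clipping percentiles to [1e-15, 1 − 1e-15];
the clamp is part of the estimator. Monte-Carlo standard errors of the
three aggregates are delete-one jackknife over replicates.

## Problem sizes

The package's reduced defaults for desk-scale verification — used by
the acceptance script and the heavier tests — are n = 500 (plus one
n = 2000 contrast), R = 100 replicates and a 100 × 50 grid, sizes at
which every qualitative ordering of the full design (strictness →
bias; flexibility → variance; True model → lowest RMSE; RMSE spike in
the extreme lower tail when a flexible SST is fitted to normal data)
is already stable and reproducible from a single seed. The full design
(R = 1000, I = 1000, J = 100, 129 conditions) is exposed through
`StudyConfig` unchanged.

## What the generator does and does not emulate

Synthetic samples share the real-data features the study is about:
smooth age trends in all four moments, skewness, heavy tails,
heteroscedasticity, realistic sample sizes, and an evenly covered age
range. They do not emulate discreteness or boundedness of raw scores,
item-level measurement error, non-uniform age sampling, covariates
beyond age, or bimodality — conclusions from passing tests therefore
concern the estimation machinery under the stated population models,
not those violations.

## Known limitations

* Numerical differentiation of the likelihood is ~2× slower than
  analytic GAMLSS scores; it buys family-agnostic correctness.
* Local (working-model) GAIC smoothing selection is a fast
  approximation to profiling the global criterion; the explicit
  `select_lambda` profiler is available when exactness matters.
* The worm plots use plain (not randomized) quantile residuals, which
  is correct for continuous scores only.
* Confidence intervals for normed scores, IRT/measurement-invariance
  questions, and alternative norming estimators are out of scope.
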