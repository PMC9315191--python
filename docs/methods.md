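# Methods

## Model

For subject *j* in cluster *i* (i = 1..r, j = 1..n_i) with observed time
t_ij = min(o_ij, c_ij) and status d_ij = I(o_ij < c_ij), the conditional
hazard is

    h(t | x, u_i, ũ_i) = h0(t e^{x̃'α + ũ_i}) e^{x'β + u_i},

so the conditional cumulative hazard has the closed form

    H(t | x, u_i, ũ_i) = H0(t e^{x̃'α + ũ_i}) e^{x'β − x̃'α + u_i − ũ_i}.

x are hazard-scale covariates, x̃ time-scale covariates (typically a
subset of x). The package estimates the two constrained subclasses that
share a single cluster effect — structure I (ũ = 0) and structure II
(ũ = u) — plus the fixed-effects reduction (`gh`). The fully general
version with two distinct, possibly correlated random effects per cluster
is out of scope: it requires bivariate numerical integration and a
dependence model for (u, ũ).

Assumptions: non-informative right censoring; clusters independent;
random effects i.i.d. from a continuous zero-mean, finite-variance
distribution G on the real line; design matrices restricted to uncensored
rows of full column rank (violations produce a warning). Ties in event
times need no special handling under a continuous parametric model.

## Baselines

Four parametric families, chosen to span the standard hazard shapes while
keeping H0 and its inverse in closed form:

| family | parameters | H0(t) | hazard shapes |
|---|---|---|---|
| Power Generalised Weibull | η, ν, δ > 0 | [1 + (t/η)^ν]^{1/δ} − 1 | incr., decr., unimodal, bathtub |
| log-logistic | μ ∈ R, τ > 0 | log(1 + e^{(log t − μ)/τ}) | decr., unimodal |
| log-normal | μ ∈ R, τ > 0 | −log Φ̄((log t − μ)/τ) | unimodal |
| gamma | shape, rate > 0 | −log Q(shape, rate·t) | monotone |

The Weibull is deliberately not offered: under the general hazard
structure it makes (α, β, θ) jointly non-identifiable. It exists only as
the δ = 1 boundary of the PGW family and is used as a numerical
cross-check in the tests. All positive parameters are optimised on the
log scale; log-hazards are computed directly (softplus/log1p forms) so
extreme time-scale shifts do not underflow.

## Marginal likelihood and integration

The cluster log-likelihood conditional on the shared effect u is
ℓ_i(η, u) = Σ_j d_ij log h(t_ij|·) − Σ_j H(t_ij|·). For structure I it
reduces algebraically to ℓ_i(u) = C_i + D_i u − B_i e^u with D_i the
cluster event count and B_i the total conditional cumulative hazard at
u = 0; the whole marginal likelihood then costs O(n) plus O(r × nodes)
per evaluation. Structure II re-evaluates the baseline at time-shifted
arguments, vectorised over subjects × quadrature nodes.

The cluster marginal likelihood m_i = ∫ e^{ℓ_i(u)} dG(u) is rescaled by
its supremum K_i = max_u ℓ_i(u) so the integrand lies in (0, 1] and
equals 1 at the inner maximiser (the raw integrand can peak at e^{-300}
for realistic cluster sizes, which destroys adaptive quadrature — the
test oracles initially demonstrated exactly this failure). Three
back-ends:

* `agh` (default): adaptive Gauss–Hermite with 25 nodes, centred at the
  mode of the log integrand with the Laplace scale 1/√(−φ''). The mode is
  located by a vectorised coarse-grid search (all clusters at once)
  refined by a Newton polish to |step| < 1e-9, so the result is smooth in
  the parameters — which keeps finite-difference gradients and Hessians
  stable. Chosen as the default because it is deterministic, ~10–50×
  faster than adaptive quadrature, and agrees with it to ~1e-6 on every
  test fixture.
* `quad`: scipy adaptive quadrature of the scaled integrand, split at the
  integrand mode into two semi-infinite panels (splitting prevents the
  global rule from missing a narrow off-centre spike).
* `mc`: plain Monte Carlo over G draws; used as the independent oracle in
  tests (agreement required within 3 Monte Carlo standard errors), never
  for fitting.

The inner maximisation over u is bracketed at ±8 prior standard
deviations (widened by a constant so weakly regularised maxima are still
found); for an all-censored cluster ℓ_i is monotone decreasing in u and
the supremum over the bracket is used — the marginal term remains well
defined and such clusters are retained.

## Estimation

The MMLE maximises Σ_i log m_i by L-BFGS-B on the unconstrained scale
(positive parameters logged; log σ_u bounded in [log 1e-6, log 50] so a
zero-variance truth can reach the boundary). Default starts: (i) a warm
start from the fixed-effects fit with σ_u = 0.2 and (ii) a null start
(zero coefficients, moment-based baseline, σ_u = 0.5); the better final
likelihood wins. The replication harness uses the warm start alone, which
on simulated benchmark-size data reaches the same optimum at half the
cost. Convergence tolerance is the L-BFGS-B relative reduction criterion
at ftol = 1e-11; non-convergence is flagged on the result, not raised.

Standard errors: numerical Hessian of the negative log marginal
likelihood at the optimum (statsmodels finite differences), inverted and
mapped to the reporting scale by the delta method (d θ/d log θ = θ). A
singular or indefinite Hessian yields NaN standard errors with a warning.

## Diagnostics

**Gradient function.** Δ(G, u) = (1/r) Σ_i exp{ℓ_i(η̂, u)}/m_i(η̂),
evaluated at the fitted parameters on a default grid of 101 points over
±4·max(σ̂_u, 0.25). The directional derivative of the marginal
log-likelihood from G towards any alternative W equals ∫Δ dW − 1, so a
curve at or below 1 means no alternative increases the likelihood; the
identity ∫Δ dG = 1 holds by construction and is verified numerically
(tolerance 1e-3) as an internal consistency check. The pointwise
statement "Δ = 1 on the support of G" holds only in the r → ∞ limit; the
implementation treats it as a plotting heuristic, and the decision rule
is based on where the curve (with its band) exceeds 1. Confidence bands
are pointwise percentile intervals from a cluster-level nonparametric
bootstrap (resample r clusters with replacement; default 200 resamples
with refitting, warm-started at η̂; a fixed-parameter variant is offered
for speed). The band quantiles include the point estimate, so bands
always contain it.

**Boundary variance test.** R_obs = max(0, 2(ℓ̂_mixed − ℓ̂_fixed)),
clipped at zero because optimisers can return tiny negative differences
for nested models. For the one-variance null (structures I/II) the
asymptotic null is ½χ²₀ + ½χ²₁, so p = ½P(χ²₁ ≥ R) for R > 0 and p = 1 at
R = 0. The two-variance mixture ¼χ²₀ + ½χ²₁ + ¼χ²₂ is implemented as pure
arithmetic even though two-effect fitting is out of scope. The mixture
weights are the large-r boundary weights; with few clusters the test is
approximate (the test suite checks the empirical level at r = 20).

## Simulator

Event times are generated exactly:
T = H0⁻¹(E e^{−(x'β − x̃'α + u − ũ)}) e^{−(x̃'α + ũ)} with E ~ Exp(1)
satisfies H(T | x, u, ũ) = E identically, which the tests verify to
machine precision. Censoring is an independent exponential whose rate is
calibrated by Brent root-finding on a 1e5-draw pilot so the expected
censored fraction hits the target.

The default design reproduces the benchmark study conditions: 24
clusters, n = 1043 split as evenly as possible (eleven clusters of 44,
thirteen of 43), PGW baseline (0.20, 1.50, 3.00), time-scale age effect
α = 0.96, hazard-scale effects β = (1.00, 0.08, 0.22, 0.10) on (age, sex,
wbc, tpi), normal random effects with σ_u ∈ {0.5, 1}, 25% censoring.
The source registry's covariate distribution is not published, so the
generator draws age, wbc, tpi ~ N(0,1) (matching their standardised use)
and sex ~ Bernoulli(1/2), independently. Consequence: bias orderings,
test power and parameter recovery are comparable with the reference
study, but absolute AIC levels are not, and the tests assert AIC only as
an ordering. Real data also have within-cluster covariate correlation and
unequal cluster sizes, which the generator does not emulate; passing
tests therefore certify the estimator under the stated design, not under
arbitrary covariate processes. Seeding: one master seed feeds a
`SeedSequence`; per-replicate streams are spawned deterministically.

## Random-effects families

Normal (default); Student-t with fixed df (default 4) scaled so
Var = σ_u² — df is fixed rather than estimated to keep ξ one-dimensional
and the boundary test well defined; two-piece normal with left/right
scales (σ1, σ2) and mode −√(2/π)(σ2 − σ1), which makes the mean exactly
zero (variance (1 − 2/π)(σ2 − σ1)² + σ1σ2). Samplers and densities are
cross-validated by Kolmogorov–Smirnov tests in the suite.

## Problem sizes used in the checks

The shipped study runs use 20 replicates of the full benchmark design
(the reference study used 250); 20 is enough for the qualitative targets
(power 1.0, bias and AIC orderings) because the effects involved are an
order of magnitude larger than their replication noise. The empirical
level of the boundary test uses 200 replicates of a smaller log-logistic
design (20 clusters of 10) where the null fit is cheap. Oracle
comparisons use 4–8 cluster fixtures with 1e6-draw Monte Carlo.

## Known limitations

* One hierarchical level, one shared random effect; no correlated
  (u, ũ) pair, no multilevel or spatial random-effects structure.
* Right censoring only; no left/interval censoring, truncation or
  time-varying covariates.
* The chi-bar mixture weights are asymptotic in r; with very few
  clusters the variance test and Wald intervals are approximate.
* AIC values depend on the covariate distribution; comparisons are only
  meaningful across models fitted to the same data.
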