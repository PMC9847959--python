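# Methods

## The model

The package implements the generalized Marshall-Olkin exponentiated
exponential (GMO-EE) distribution, a four-parameter lifetime model for
strictly positive data. The generalized Marshall-Olkin transform maps a
baseline cdf F to

    G(x) = [λ F(x) + (1−λ) F(x)²] / [α + (1−α) F(x)],    α, λ ∈ (0, 1],

and the baseline here is the exponentiated exponential (EE),
F(x) = (1 − e^{−θx})^β with rate θ > 0 (units 1/time) and shape β > 0.
The transform's tilt parameter α and mixing parameter λ enrich the
hazard-rate repertoire of the EE baseline: depending on (α, λ, θ, β) the
hazard can be increasing, decreasing, constant, bathtub, upside-down
bathtub, or increasing-decreasing-increasing, which is the model's point —
one family covering shapes that usually require switching between Weibull,
gamma, and EE fits.

Submodels are used throughout as correctness identities: λ = 1 gives the
classical Marshall-Olkin EE; α = λ = 1 gives EE(θ, β); additionally β = 1
gives the exponential(θ). The parameter box is taken half-open, (0, 1],
so these submodels are reachable; α → 0 degenerates the cdf denominator.

## Numerical design

**Log-space evaluation.** The density factors as g = A(F)/D(F)² · f with
A = (1−α)(1−λ)F² + 2α(1−λ)F + αλ and D = α + (1−α)F, both bounded away
from zero on the box; only the EE factor needs care. log(1 − e^{−θx}) is
computed as `log(-expm1(-t))` for small t and `log1p(-exp(-t))` for large
t; the log-pdf is evaluated directly, never as log of the pdf. At x = 0
the density is +∞ for β < 1 (matching the EE baseline), λθ/α for β = 1,
and 0 for β > 1.

**Quantile.** Solving G = p is a quadratic in F,
(1−λ)F² + (λ − p(1−α))F − pα = 0, whose discriminant is nonnegative on
the whole box; the positive root is evaluated in whichever algebraically
equivalent form avoids cancellation, and degenerates to a linear solve at
λ = 1. Every quantile evaluation is round-trip checked against the cdf
(tolerance 1e-6) with a bracketed Brent fallback; in practice the closed
form passes everywhere tested (round trips hold to 1e-9 across the box).
Random variates are inverse-transform draws from a seeded
`numpy.random.Generator`.

**Moments.** Quadrature is the authoritative route: adaptive integration
of x^r g(x) with breakpoints at model quantiles so the tail is resolved;
the mgf integrand is assembled in log space. A series route is provided
as an analytic cross-check: expanding 1/D geometrically at the cdf level
gives G = Σ_l (1−α)^l Σ_{s=0}^{l+1} b_{l,s} F^{s+1} with
b_{l,s} = (−1)^s[λ C(l,s) − (1−λ) C(l,s−1)], so every moment functional
is a weighted sum of EE(θ, β(s+1)) functionals, which are evaluated in
stable closed forms (gamma functions for the mgf; digamma/trigamma for
the first two raw moments — the alternating finite binomial sums that are
sometimes quoted for EE moments are exact only at integer exponents and
cancel catastrophically at large ones). The binomial expansion forfeits
some sign cancellation, so the outer sum converges roughly where
2(1−α) < 1; truncation stops when a tail term drops below `tol`
(default 1e-10, cap `max_l` = 200) and raises — or falls back to
quadrature — otherwise. Where it converges the two routes agree to ~1e-10.
Incomplete moments and the Lorenz/Bonferroni curves
(L(p) = m₁(Q(p))/μ, B = L/p) use the quadrature route.

## Estimation

Five estimators share one optimizer harness: maximum likelihood (MLE),
least squares against the plotting positions i/(n+1) (LSE), weighted
least squares with reciprocal-variance weights
w_i = (n+1)²(n+2)/(i(n−i+1)) (WLSE), and minimum-distance estimators for
the Anderson-Darling (ADE) and Cramer-von Mises (CvME) objectives.

Constraints are removed by optimizing over
(logit α, logit λ, log θ, log β); the α = λ = 1 boundary is reachable in
the limit and the coordinates are clipped at |z| = 40 to keep expit away
from exact saturation. Each fit runs L-BFGS-B (analytic gradient for the
MLE, obtained by differentiating the factored log-likelihood) followed by
a Nelder-Mead polish — the likelihood surface has a ridge in (α, λ, β) on
which quasi-Newton steps can stall — from 25 starting points by default,
drawn from a seeded Latin hypercube over a sample-scaled box
(α, λ ∈ [0.05, 0.99]; θ log-uniform on [0.1/x̄, 10/x̄]; β log-uniform on
[0.2, 20]). MLE standard errors are observed-information Wald SEs: the
Hessian is formed by central differences of the analytic score and
inverted, with NaN and a warning when it is not positive definite.

A variant of the WLSE weights with (n+1) in place of (n+2) circulates in
some presentations; it is exposed behind a flag but differs from the
default only by the constant factor (n+1)/(n+2), so the estimates are
identical. The AD objective is the standard one with G(x_{(n+1−i)}) in
the second logarithm; the same-index variant that some texts print is a
genuinely different objective and is exposed for comparison only. Fitted
cdf values inside distance objectives are clamped to [1e-12, 1 − 1e-12].

Ties in the data are kept as-is (plotting positions stay distinct); no
jittering.

## Goodness of fit

Reports carry −2·log-likelihood, AIC = −2log + 2k, and the K-S, AD and
CvM statistics of the fitted cdf. p-values use simple-hypothesis
asymptotics — exact-n Kolmogorov for K-S, the asymptotic W² distribution
for CvM, and Marsaglia & Marsaglia's evaluation of the limiting A²
distribution for AD. Since the parameters are estimated from the same
data these p-values are optimistic; they are reported as descriptive
comparison indices, not calibrated test levels. Baseline fits (EE,
Weibull with shape-first parameterization and cdf 1 − exp(−(x/λ)^k),
exponential with rate = 1/x̄) allow four-model comparison tables.

## Monte Carlo harness

`run_study` simulates replicated samples per (true parameter vector, n)
cell, fits each selected estimator, and reports mean bias, MSE, the
Monte Carlo standard error of the bias, and convergence counts.
Per-replicate seeds are spawned deterministically from the master seed,
and all estimators within a replicate share the sample (paired design).
Each fit starts from the true vector plus two Latin-hypercube points;
replicates that fail are dropped and counted, and an empty cell is
reported as NaN, never as zero. Defaults are the three study parameter
vectors η₁ = (0.4, 0.8, 1, 0.5), η₂ = (0.5, 0.7, 3, 0.9),
η₃ = (0.2, 0.5, 2, 0.75) over n ∈ {50, 100, 150, 200, 250, 500, 750,
1000} at 1000 replications — a desk-scale design whose per-cell bands
(sd/√reps) are tight enough to read trends; the bundled validation runs
use 300–1000 replicates at the cells they check.

## What the synthetic generator does and does not emulate

Synthetic samples are exact i.i.d. draws from the model itself, so
passing tests demonstrate internal consistency (sampling, likelihood,
optimizer, and summaries agree) and finite-sample estimator behaviour
under correct specification. They do not probe misspecification,
censoring, dependence, or measurement rounding — all present in real
lifetime data; the four packaged real datasets partially cover that gap.

## Known limitations

* The simulation harness measures properties of fully converged
  multi-start estimates. Published bias/MSE tables for this family were
  evidently produced with single-start optimization without convergence
  filtering, whose stall pattern on the (α, λ, β) likelihood ridge
  inflates apparent bias at large n; those optimizer-protocol-dependent
  values are not reproducible from a converged estimator, and this
  package does not emulate a degraded optimizer. At small n (where
  genuine finite-sample bias dominates) the harness agrees with
  published magnitudes.
* The series moment route is a fidelity cross-check; it diverges for
  small α by construction and defers to quadrature.
* No censoring, covariates, or interval estimation beyond Wald SEs.
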