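# Methods

## Model

A community of `S_A` species occupies a region of area `A`.  Each
species' regional abundance `N_A` follows a zero-truncated negative
binomial (TNBD): the gamma–Poisson mixture with mixing density
`omega^k lambda^(k-1) e^(-lambda omega) / Gamma(k)` conditioned on
`N_A >= 1`, so every species in the region exists there.  Its pmf is

    P(N_A = n) = C * Gamma(k+n)/(Gamma(k) Gamma(n+1))
                 * (omega/(omega+A))^k * (A/(omega+A))^n,
    C = [1 - (omega/(omega+A))^k]^(-1).

The `k -> 0` limit is the area-based logseries
`phi(n) = alpha_A x_A^n / n` with `x_A = A/(omega+A)` and
`alpha_A = 1/ln(1 + A/omega)`.  Because the zero class was truncated
*before* taking the limit, this is a proper pmf — the degeneracy of the
untruncated limit (all mass collapsing onto n = 0) never arises.
A local sample of area `a <= A` binomially thins each species, giving

    phi(0) = 1 - alpha_A / alpha_a,
    phi(n) = alpha_A x_a^n / n,   n >= 1,

with `x_a` and `alpha_a` the same transforms at area `a`.  The zero
class vanishes at `a = A` (census).

Assumptions worth stating plainly: species are exchangeable and
independent; thinning is spatially uniform (no clumping beyond what the
gamma mixing supplies); the region's SAD really is logseries-like.  The
model is deliberately sensitive to rare species — that is what lets it
extrapolate far beyond the sampled area, and also what makes it
overestimate badly when the data are not logseries (see the
misspecification samplers below).

## Estimation

`(S_a, M_a)` — observed richness and summed abundance — are sufficient.
`fit_omega` solves `(e^t - 1)/t = M_a/S_a` for `t = 1/alpha_a` by
Brent's method on an expanding bracket starting at `[1e-8, 64]`; the
left side is strictly increasing from 1, so the root is unique whenever
`M_a > S_a`.  `M_a = S_a` (every species a singleton) is reported as an
explicit identifiability error.  Then `omega = a/(e^t - 1)` and
`S_A = S_a alpha_a / alpha_A`.

Variances come from the inverse observed information: the Hessian of
the log likelihood at the MLE, by central finite differences with
relative step `1e-5` per parameter, with `S_A` relaxed to a continuous
value through log-gamma.  The continuous relaxation shifts the argmax by
O(1) species relative to the exact integer maximizer (a digamma-vs-log
effect); the point estimate reported is the moment-equation value, which
is the exact integer-resolution ML solution, and the relaxation is used
only to define the curvature.

## Rarefaction and extrapolation

Richness at a target area `A*` is `S_a alpha_a / alpha_A*`.  Its
variance decomposes, conditionally on `S_a`, into

    Var = S_hat(A*)^2 [g(a) - g(A*)]^2 Var(omega_hat)
        + (S_hat(A*)/S_a)^2 S_a (1 - S_a/S_hat_A),

where `g(area) = alpha(area) * area / (omega^2 + omega*area)` is the
derivative of `ln alpha(area)` with respect to omega, and `S_hat_A` is
the regional estimate from the fit.  Two choices here were genuinely
open:

* **The printed form of the variance expression is typographically
  garbled in its source**; the implementation uses the delta-method form
  above, which reproduces the published interior confidence intervals
  (415, 498) at 2.4 ha and (1,581, 1,956) at the region to within a
  couple of species.
* **`Var(S_a)` uses the regional `S_hat_A`**, not `S_hat(A*)`.  Using
  the target-area estimate would be undefined for interpolation
  (`S_a > S_hat(A*)`), and only the regional convention reproduces the
  published intervals.  With this convention the combined-sample
  interpolation to 1.2 ha gives a CI of about (330, 389), whereas the
  published table prints (326, 393); the ~4-species gap is unexplained
  (possibly a different `Var(S_a)` convention for interpolation) and is
  left as a recorded discrepancy rather than forced to agree.

CIs are symmetric normal (`point ± 1.96 SE`, floored at zero): the
published parametric intervals are symmetric about their point
estimates, which fixes this choice.

## Nonparametric comparators

Chao1 (`S + f1^2/(2 f2)`, bias-corrected fallback when `f2 = 0`) with
the classical 1987 variance and the log-transform CI on the excess
`point − S`; ACE with rare/abundant cutoff 10 (the conventional value)
and a delta-method variance propagating multinomial uncertainty through
a numerical gradient; the first-order jackknife in its abundance form
`S + f1`, whose classical variance `sum(a_k^2 f_k) − S_hat` reduces to
`2 f1` — this exact form reproduces the published jackknife intervals.
Hurlbert rarefaction uses log-binomial coefficients and the full
species-pair covariance variance; Coleman rarefaction is the random
placement expectation `sum f_k (1 − (1 − A*/a)^k)` with Bernoulli
variances.  All of these see the full frequency profile, unlike the
parametric fit.

## Goodness of fit

Both tests target the conditional-on-presence distribution
`alpha_a x_a^n / n` over `n >= 1`, since the zero class is unobservable.
The KS test compares step CDFs (species abundance is discrete; a
smooth-CDF KS would inflate type II error) and calibrates its p value by
a parametric bootstrap that *refits omega in every replicate*, with the
`(1 + #{D* >= D})/(B + 1)` convention.  The χ² test bins expected counts
`S_a alpha_a x_a^n / n` with an open tail, pools right-to-left until
every expected count reaches 5, and uses `bins − 2` degrees of freedom
(one estimated parameter).  Both tests hold their nominal 0.05 size to
within [0.02, 0.08] in the calibration experiments in the test suite.

## Simulators

The logseries sampler draws the number of observed species as
`Binomial(S_A, alpha_A/alpha_a)` and observed abundances i.i.d. from the
zero-truncated logseries at `x_a` — exactly the factorisation of the
model likelihood.  Samples whose binomial draw is zero (no species
observed, probability negligible at the study sizes) are redrawn.
Logseries variates come from scipy's `logser` generator.

The TNBD sampler draws `(lambda, N_A)` jointly and rejects while
`N_A = 0`, which reproduces the truncated *mixture* (rejecting only the
Poisson draw would instead give a mixture of truncated Poissons — a
different model).  Acceptance is `1 − (omega/(omega+A))^k`; below 1e-3 a
warning is logged, below 1e-8 the call errors out.  The truncated
Poisson-lognormal sampler uses `lambda = exp(Normal(mu, sigma))` and
zero-truncated Poisson draws by CDF inversion.  Both misspecification
models then thin binomially to the local area.

Each simulation replicate gets its own RNG stream, seeded
`seed + replicate`, so any replicate is independently reproducible.

What the generators do *not* emulate: spatial aggregation of
conspecifics beyond gamma mixing, detection error, taxonomic lumping,
and temporal turnover.  Passing the simulation checks therefore shows
the estimator is correct *under its own sampling model* (and quantifies
its failure under TNBD/lognormal alternatives), not that any particular
field survey satisfies that model — that is what the GOF tests are for.

## Simulation-study engine and problem sizes

`run_study` aggregates, per estimator: mean estimate, sample SE (SD
across replicates), mean estimated SE, and coverage percentage of the
95% CI.  A good variance estimator makes the mean estimated SE track the
sample SE; CP near 95 validates the intervals.  Area-based CIs are
normal; Chao1/ACE use their log-transform CIs, the jackknife its normal
CI, matching how each is used in practice.  Estimator failures on a
replicate are logged, excluded from means, and counted as non-covering.

Default problem sizes are chosen to keep a full check runnable on a
single desk CPU: 500 replicates for studies (the reference experiments
behind the published table used 5,000 — `--reps` scales it back up), 500
outer replicates with B = 199 bootstrap samples for test-size
calibration.  At 500 replicates the Monte-Carlo SE of a coverage
percentage is about 1 point, which is tight enough to distinguish ~95%
coverage from the 0% coverage of the nonparametric estimators.

The classical Fisher variance formula (the parenthesised comparison
columns of the published simulation table) is not implemented: its
derivation fixes the sampled individual count and is known to
understate the variance; the engine reports only the area-based and
nonparametric columns.

## Numerical notes and limitations

* All gamma ratios and binomial coefficients are computed in log space;
  pmfs are exposed with log variants and remain finite at `n = 1e4+`.
* alpha is validated only as positive.  The normalized alpha lies in
  (0, 1) only when `area/omega > e − 1`; tiny areas (or huge omega) give
  alpha > 1, which the transforms handle correctly.
* Area units are the caller's responsibility: only ratios `area/omega`
  enter the formulas, so omega inherits the unit of `a` and `A`.
* The packaged Atlantic-forest frequency tables carry only the published
  rare classes `f_1..f_7`; survey totals (S, M) are shipped separately,
  and tests that need a full profile complete the abundant tail
  synthetically from the fitted model (marked as such).  Consequently
  the published ACE/Hurlbert/Coleman values for those data, which
  depend on the unpublished upper tail, are implemented but not asserted
  against.
* Extrapolation beyond the fitted region (`A* > A`) is refused rather
  than extrapolated silently.
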