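# arealog

**Area-based Fisher's logseries for rarefaction and extrapolation of
species richness.**

`arealog` is for ecologists and biostatisticians who need to compare or
predict species richness across surveys of *different sampled areas* —
e.g. extrapolating tree richness from a 1.2-ha transect to a
67,000-ha fragment landscape — with honest standard errors.

## The model

The classical logseries predicts the number of species with abundance
*n* as proportional to *x*ⁿ/*n*, governed by Fisher's α.  That model
has no notion of area: α fitted on a 1-ha plot and α fitted on a 10-ha
plot are not comparable, and the classical variance formula badly
understates the uncertainty of richness extrapolations.

`arealog` instead models the regional abundance *N_A* of a species in a
region of area *A* by a zero-truncated negative binomial (a truncated
gamma–Poisson mixture) with aggregation *k* and scale ω.  Letting
*k* → 0 gives a proper pmf,

    φ(n | A, ω) = α_A x_A^n / n,   n = 1, 2, ...
    x_A = A / (ω + A),   α_A = 1 / ln(1 + A/ω),

where α_A is a *normalized*, area-dependent Fisher's alpha.  A local
sample of area *a* ≤ *A* follows the same family with an explicit
unseen-species class φ(0) = 1 − α_A/α_a.  The observed richness *S_a*
and abundance total *M_a* are sufficient: the MLEs solve

    M_a / S_a = α_a (e^{1/α_a} − 1),      Ŝ_A = S_a α̂_a / α̂_A,

and richness at any target area *A*\* in (0, *A*] is

    Ŝ_{A*} = S_a α̂_a / α̂_{A*},

interpolating below *a* and extrapolating above it.  Variances combine
the observed-information variance of ω̂ (delta method) with the binomial
sampling variance of *S_a*, giving asymptotically unbiased SEs and
symmetric 95% CIs.

Alongside the parametric model the package provides the standard
nonparametric estimators (Chao1, ACE, first-order jackknife), Hurlbert
individual-based and Coleman area-based rarefaction, discrete
Kolmogorov–Smirnov (parametric bootstrap) and χ² goodness-of-fit tests,
seeded community simulators (logseries, truncated negative binomial,
truncated Poisson-lognormal), and a replicated simulation-study engine
reporting bias, SE calibration and CI coverage.

## Worked example

Brazilian Atlantic forest interior transects: 371 tree species among
2,174 stems on 1.2 ha, inside a 67,282.16-ha fragment region.

```sh
arealog fit --S 371 --M 2174 --a 1.2 --A 67282.16 --format json
```

```json
{
  "omega_hat": 0.07097803657980459,
  "omega_ci_low": 0.05558334726033219,
  "omega_ci_high": 0.08637272589927698,
  "S_A_hat": 1769.6401889059937,
  "S_A_ci_low": 1582.0876976534632,
  "S_A_ci_high": 1957.1926801585241
}
```

ω̂ ≈ 0.071 (95% CI 0.056–0.086) is the area scale at which half the
regional individuals of a species would fall inside ω hectares; the
region is predicted to hold ≈ 1,770 tree species (CI 1,582–1,957) —
roughly 3.5× what Chao1 or the jackknife report from the same sample,
which is the expected behaviour of those lower-bound estimators under a
rare-species-rich logseries community.  Doubling the area instead:

```sh
arealog extrapolate --S 371 --M 2174 --a 1.2 --A 67282.16 --A-star 2.4 --format json
```

predicts 456.5 species (CI 414.9–498.1) at 2.4 ha; the richness actually
observed when the edge transects are pooled in is 443, inside the
interval.  The same library calls are available in Python:

```python
from arealog import SurveyDesign, fit_full, estimate_at_area

fit = fit_full((371, 2174), SurveyDesign(a=1.2, A=67282.16))
est = estimate_at_area(fit, 2.4)
print(round(est.point), round(est.ci_low), round(est.ci_high))  # 456 415 498
```

Before trusting an extrapolation, check the model: the singleton to
doubleton ratio f₁/f₂ should be near 2, and `arealog gof` runs the
discrete-KS and χ² tests against the fitted conditional logseries.

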