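# gmoee

A Python implementation of the **generalized Marshall-Olkin exponentiated
exponential (GMO-EE) distribution** — a four-parameter lifetime model for
positive data — with full distribution machinery, five frequentist
estimators, goodness-of-fit reporting, a Monte Carlo estimator-comparison
harness, and four packaged benchmark datasets. It is aimed at
statisticians and reliability/survival analysts who need a single family
whose hazard rate can be increasing, decreasing, constant, bathtub,
upside-down bathtub, or increasing-decreasing-increasing.

## The model

The generalized Marshall-Olkin transform maps a baseline cdf F to

```
G(x; α, λ) = [λ F(x) + (1 − λ) F(x)²] / [α + (1 − α) F(x)],   α, λ ∈ (0, 1],
```

with tilt α and mixing λ (λ = 1 recovers the classical Marshall-Olkin
family). Taking the exponentiated exponential baseline
F(x) = (1 − e^{−θx})^β gives GMO-EE(α, λ, θ, β). Setting α = λ = 1
recovers EE(θ, β); additionally β = 1 recovers the exponential(θ).
The package provides:

* `gmoee.core` — pdf/cdf/survival/hazard/log-density, a closed-form
  quantile with a root-finding safety net, and seeded inverse-transform
  sampling;
* `gmoee.moments` — mgf, raw/incomplete moments, variance,
  Lorenz/Bonferroni curves, each via authoritative quadrature and a
  series expansion cross-check;
* `gmoee.estimation` — MLE (analytic score, observed-information SEs),
  least squares and weighted least squares against plotting positions,
  and minimum-distance Anderson-Darling / Cramer-von Mises estimators,
  all through one multi-start constrained optimizer harness;
* `gmoee.gof` — −2log, AIC, K-S/AD/CvM statistics with approximate
  p-values, plus EE/Weibull/exponential baseline fits for comparison
  tables;
* `gmoee.montecarlo` — seeded bias/MSE simulation studies over a
  (parameter vector × n × estimator) grid;
* `gmoee.datasets` — four classic positive datasets (air-conditioning
  failures, NYC ozone, Wheaton River floods, COVID-19 recovery times)
  as checksummed text fixtures;
* a `gmoee` command line (`fit`, `gof`, `simulate`, `rvs`, `describe`).

See `docs/methods.md` for the numerical design and its assumptions.

## Worked example

Fit all four models to the packaged recovery-time dataset (50 male
COVID-19 patients over 60, days from first positive to first negative
PCR test):

```
$ gmoee gof --fixture covid_recovery_m60 --starts 10 --seed 1
      model    -2log      AIC     AD    CvM    K-S  p(AD)  p(CvM)  p(K-S)
     GMO-EE 346.7802 354.7802 0.2113 0.0276 0.0690 0.9870  0.9834  0.9577
         EE 352.0952 356.0952 0.6886 0.1115 0.1155 0.5685  0.5313  0.4822
    Weibull 363.4034 367.4034 1.4451 0.2290 0.1465 0.1902  0.2177  0.2115
Exponential 391.1263 393.1263 6.3070 1.2118 0.3472 0.0007  0.0008  0.0000
```

The GMO-EE fit dominates the nested EE and exponential models and the
Weibull on every distance statistic (smaller AD/CvM/K-S; higher
p-values). The fitted parameters and what they imply:

```
$ gmoee fit --fixture covid_recovery_m60 --seed 1
MLE  alpha=0.0551 (0.0548)  lambda=0.6797 (0.1967)  theta=0.1079 (0.0281)  beta=9.8301 (3.6947)
     loglik=-173.3901  -2log=346.78

$ gmoee describe --eta 0.0551,0.6796,0.1079,9.8323
mean=18.3525
variance=108.7629
sd=10.4289
q25=11.1883
q50=14.9738
q75=22.5999
```

So under the fitted model the mean recovery time is about 18.35 days
with median 15 days, and the fitted probability of recovery within two
weeks is `gmoee_cdf(14.0, eta)` ≈ 0.4462, i.e. 44.6 %.

Library use mirrors the CLI:

```python
from gmoee import datasets, fit_mle, gmoee_cdf
from gmoee.moments import raw_moment

sample = datasets.load("covid_recovery_m60")
fit = fit_mle(sample, starts=25, seed=1)
print(fit.eta_hat, -2 * fit.objective_value)
print(raw_moment(1, fit.eta_hat).value)       # mean recovery time, days
print(100 * gmoee_cdf(14.0, fit.eta_hat))     # % recovered within 2 weeks
```

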