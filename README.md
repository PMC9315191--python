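# megh — mixed-effects general hazard models for clustered survival data

Survival data often come grouped: patients treated in different hospitals,
or living in different administrative districts. Ignoring the resulting
between-cluster heterogeneity biases hazard-regression estimates and
understates their uncertainty. `megh` implements a parametric
**mixed-effects general hazard (MEGH)** model for right-censored clustered
time-to-event data, aimed at biostatisticians and epidemiologists who want
a fully parametric, likelihood-based alternative to semiparametric frailty
models.

## The model

For subject *j* in cluster *i* the conditional hazard is

    h(t | x_ij, u_i, ũ_i) = h0( t · exp(x̃_ij'α + ũ_i) ) · exp(x_ij'β + u_i)

with closed-form cumulative hazard

    H(t | x_ij, u_i, ũ_i) = H0( t · exp(x̃_ij'α + ũ_i) )
                            · exp(x_ij'β − x̃_ij'α + u_i − ũ_i).

Covariates act on the **hazard scale** (β) and on the **time scale** (α);
the zero-mean cluster random effects u, ũ do the same. The structure nests
proportional hazards (α = 0), accelerated failure time (α = β) and
accelerated hazards (β = 0), with or without frailty. Two tractable
subclasses share a single random effect per cluster:

* **structure I** (`megh1`): ũ_i = 0 — generalises mixed-effects PH;
* **structure II** (`megh2`): ũ_i = u_i — generalises mixed-effects AFT;
* `gh`: no random effects.

Baselines h0 are flexible parametric families — Power Generalised Weibull,
log-logistic, log-normal, gamma (the Weibull is excluded: it makes the
general hazard structure non-identifiable). Estimation maximises the
**marginal likelihood**, m(η) = ∏_i ∫ exp{ℓ_i(η, u)} dG(u; ξ), with the
per-cluster integral rescaled by its supremum for numerical stability and
evaluated by adaptive Gauss–Hermite quadrature. Standard errors come from
the inverse numerical Hessian via the delta method.

The package also provides

* the **gradient-function diagnostic** Δ(G, u) = (1/r) Σ_i exp{ℓ_i(u)}/m_i
  for the assumed random-effects distribution (values above 1 indicate G
  can be improved), with cluster-bootstrap confidence bands;
* the **boundary likelihood ratio test** for H0: σ_u² = 0, using the
  chi-bar-square null ½χ²₀ + ½χ²₁ (and ¼χ²₀ + ½χ²₁ + ¼χ²₂ for the
  two-variance case);
* an **exact simulator** for clustered survival data by inversion of the
  closed-form cumulative hazard, plus a replication-study harness.

## Worked example

```python
import numpy as np
from megh import MEGHModel, table1_design, simulate_dataset

# 24 clusters, n=1043, PGW baseline (0.20, 1.50, 3.00), alpha=0.96,
# beta=(1.00, 0.08, 0.22, 0.10), normal random effects sd=1, 25% censoring
design = table1_design(structure="megh1", sigma_u=1.0)
data = simulate_dataset(design, seed=42)

# fit(X, y, groups=...) with array/DataFrame covariates also works;
# a ClusteredDataset carries times, statuses, clusters and both designs
est = MEGHModel(structure="megh1", baseline="pgw").fit(data)
print(est.result_.summary().round(3))
print(f"loglik={est.loglik_:.2f}  AIC={est.aic_:.2f}  sd_u={est.re_sd_:.3f}")
```

Output:

```
           estimate     se  ci_low  ci_high
age           0.992  0.041   0.911    1.072
sex           0.116  0.073  -0.028    0.260
wbc           0.249  0.037   0.176    0.322
tpi           0.116  0.039   0.039    0.193
alpha:age     1.006  0.103   0.805    1.208
eta           0.200  0.031   0.140    0.260
nu            1.609  0.101   1.410    1.807
delta         3.668  0.436   2.814    4.522
sd_u          0.932  0.143   0.651    1.212
loglik=-446.63  AIC=911.26  sd_u=0.932
```

The hazard-scale coefficients (age 0.99, sex 0.12, wbc 0.25, tpi 0.12),
the time-scale age effect (1.01), the baseline parameters and the
random-effect standard deviation (0.93) all recover the generating values
within sampling error. The boundary test then confirms the random effect:

```python
from megh import lrt_random_effect
res = lrt_random_effect(data, structure="megh1")
print(f"R_obs={res.r_obs:.1f}  p={res.p_value:.2e}")   # R_obs=397.1  p=1.20e-88
```

The same workflow is available from the shell:

```bash
megh simulate --structure megh1 --sigma-u 1.0 --seed 42 --out data.csv
megh fit --data data.csv --structure megh1 --baseline pgw \
     --x age,sex,wbc,tpi --xtilde age --out fit.json
megh test-re --data data.csv --structure megh1 --x age,sex,wbc,tpi --xtilde age
megh diagnose gradient --data data.csv --structure megh1 \
     --x age,sex,wbc,tpi --xtilde age --boot 200 --seed 1 --out curve.csv
```

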