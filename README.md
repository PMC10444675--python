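# ddrm — item response models for slider and interval responses

`ddrm` implements two item response theory (IRT) models for continuous
bounded response formats, together with simulation, analytic item
information, Bayesian estimation, and model evaluation:

- the **Beta Response Model (BRM)** for single-range-slider responses
  (one value on a 0–100 scale), and
- the **Dirichlet Dual Response Model (DDRM)** for dual-range-slider
  (RS2) *interval* responses, where a respondent sets a lower and an upper
  bound to express not only the central tendency of a trait but also its
  variability (or their uncertainty).

The package is aimed at psychometricians and methodologists who want to
score interval-response questionnaires, run parameter-recovery studies for
such designs, or study the scale-inherent coupling of interval location and
interval width that raw mean scores suffer from.

## The models

A raw single response $X^* \in \{0,\dots,100\}$ is rescaled to the open unit
interval, $X = (X^*+1)/102$, and modelled as

$$X_{ij} \sim \mathrm{Beta}(m_{ij}, n_{ij}), \qquad
m_{ij} = \exp[\alpha(\theta_i-\delta_j)+\tau_j], \quad
n_{ij} = \exp[-\alpha(\theta_i-\delta_j)+\tau_j],$$

with person location $\theta_i$, item difficulty $\delta_j$, item precision
$\tau_j \ge 0$ and scaling $\alpha > 0$.

An interval response with raw bounds $Y^*_L \le Y^*_U$ is rescaled via
$Y_L = (Y^*_L+1)/103$, $Y_U = (Y^*_U+2)/103$ (so that $0 < Y_L < Y_U < 1$
strictly, even for zero-width raw intervals) and represented as the simplex
vector $\boldsymbol{Y} = (Y_L,\; Y_U-Y_L,\; 1-Y_U)$ — the proportions of the
scale left of, inside, and right of the interval. The DDRM models it as

$$\boldsymbol{Y}_{ij} \sim \mathrm{Dir}(a_{ij}, e_{ij}, d_{ij}), \qquad
\begin{aligned}
a_{ij} &= \exp[\alpha_\lambda(\theta_i-\delta_j)+\tau_j],\\
e_{ij} &= \exp[\alpha_\epsilon(\eta_i+\gamma_j)+\tau_j],\\
d_{ij} &= \exp[-\alpha_\lambda(\theta_i-\delta_j)+\tau_j],
\end{aligned}$$

where $\eta_i$ is a person's expansion tendency (wide vs. narrow intervals)
and $\gamma_j$ an item's tendency to elicit wide intervals. Closed-form
Fisher item information for $\theta_i$ and $\eta_i$ is available through
digamma/trigamma identities (`ddrm.information`).

Estimation is Bayesian, via the package's own No-U-Turn sampler with
analytic gradients (`ddrm.inference`); a joint hierarchical BRM+DDRM model
links person parameters $(\theta^B_i, \theta^D_i, \eta^D_i)$ through a
multivariate-normal prior with an LKJ-Cholesky(1) correlation prior.

## Worked example

```python
import numpy as np
from ddrm import (generate_dataset, fit_ddrm, MCMCConfig, PriorSpec,
                  convergence_report, point_estimates, manifest_dependence,
                  latent_dependence)

ds = generate_dataset(n_persons=50, n_items=8, seed=7)     # simulate RS2 data
print(round(manifest_dependence(ds), 2))                   # -0.72
print(round(latent_dependence(ds.design.theta, ds.design.eta), 2))  # -0.01

fit = fit_ddrm(ds.responses, PriorSpec.simulation(),
               MCMCConfig(n_chains=2, n_warmup=250, n_sampling=250, seed=11))
conv = convergence_report(fit, context="simulation")
print(conv.passed, conv.n_divergent)                       # True 0

med = point_estimates(fit)
print(round(np.corrcoef(med["theta"], ds.design.theta)[0, 1], 2))  # 0.97
print(round(np.corrcoef(med["eta"], ds.design.eta)[0, 1], 2))      # 0.93
print(round(latent_dependence(med["theta"], med["eta"]), 2))       # 0.02
```

The first two numbers illustrate the motivating artifact: the *manifest*
person-level correlation between mean interval width and mean absolute
deviation of the interval midpoint from the scale centre (ADSM) is strongly
negative (−0.72) although the *generating* traits are uncorrelated (−0.01).
After fitting, posterior-median person parameters track the truth closely
(correlations 0.97 and 0.93), and the recovered |θ̂|–η̂ correlation (0.02)
stays near the generating value rather than the manifest −0.72.

The same steps are available from the shell:

```sh
ddrm simulate --I 100 --J 10 --seed 1 --out data.csv
ddrm fit --data data.csv --model ddrm --seed 1 --out fit
ddrm info --out curves.csv
ddrm recover --conditions 100x10 --reps 3 --seed 7 --out recovery/
```

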