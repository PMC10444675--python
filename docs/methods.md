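# Methods

## Models

The package implements two IRT models for continuous bounded response
formats. For single-range-slider (RS1) responses, the Beta Response Model
(BRM) treats the transformed response $X \in (0,1)$ as
$\mathrm{Beta}(m_{ij}, n_{ij})$ with
$m_{ij} = \exp[\alpha(\theta_i-\delta_j)+\tau_j]$ and
$n_{ij} = \exp[-\alpha(\theta_i-\delta_j)+\tau_j]$. For dual-range-slider
(RS2) interval responses, the Dirichlet Dual Response Model (DDRM) treats
the three scale proportions (left of, inside, right of the interval) as
$\mathrm{Dir}(a_{ij}, e_{ij}, d_{ij})$ with the link functions described in
the README. Both links enforce the identities
$m_{ij} n_{ij} = a_{ij} d_{ij} = e^{2\tau_j}$: the precision parameter
scales all shapes jointly, tightening the response distribution without
moving its mean.

The motivating assumption is that an interval's location measures the
central tendency of a latent state distribution while its width measures
that distribution's spread (or the respondent's uncertainty — the model
cannot distinguish the two; validation of the interpretation is an
empirical matter, not a modelling one). Because the Dirichlet respects the
scale's sum constraint, the latent location and expansion dimensions are
separated even though the manifest location and width are mechanically
coupled on a bounded scale.

### Response-scale transforms

Raw 0–100 responses are mapped strictly inside the unit interval —
$X=(X^*+1)/102$ for RS1; $Y_L=(Y^*_L+1)/103$, $Y_U=(Y^*_U+2)/103$ for RS2 —
so that log-likelihoods remain finite and zero-width raw intervals acquire
a positive width of $1/103$. Boundary-valued inputs to the likelihood are
rejected with a pointer to these transforms rather than nudged silently;
nudging is a data-preparation decision the caller should make explicitly.
Both transforms are exactly invertible on the integer grid (verified for
all 5151 admissible RS2 pairs).

### Item information

Expected Fisher information for $\theta_i$ and $\eta_i$ has closed form:
the expectation of the data-dependent score terms vanishes at the true
parameters, leaving only trigamma curvature terms,

$$\mathcal I_\eta = -\bigl[\psi'(a+e+d) - \psi'(e)\bigr]\,
\alpha_\epsilon^2 e^2 ,$$

and the analogous two-term expression for $\theta$ (with the $a$/$d$
tandem). The implementation evaluates these directly with
`scipy.special.polygamma`; a brute-force Monte-Carlo Fisher oracle (central
second differences of the log-likelihood at sampled responses, step
$10^{-3}$ on the latent scale) lives in the test-suite and confirms the
closed forms within 3 Monte-Carlo standard errors on randomized parameter
grids. The characteristic shapes — $\theta$-information unimodal at low
expansion but U-shaped at high expansion, constant at
$\theta_i-\delta_j=0$; $\eta$-information monotone in $\eta_i+\gamma_j$ and
raised by $|\theta_i-\delta_j|>0$ — are asserted as grid properties.

## Synthetic data

`ddrm.simulation` generates data under the recovery-study design:
$\theta_i, \eta_i \sim \mathcal N(0,1)$; $\delta_j$ and $\gamma_j$ drawn
from the fixed candidate grid spanning $[-2,2]$ with step $4/J$;
$\tau_j \sim \mathcal U(0,2)$; $\alpha_\lambda = \alpha_\epsilon = 0.5$.
These defaults are the study conditions and are not tuned. Two choices the
design description leaves open:

- **Grid assignment.** Item parameters are assigned by drawing a random
  permutation of the $(J{+}1)$-value grid independently for $\delta$ and
  $\gamma$ and keeping the first $J$ values (sampling without replacement).
  This keeps the spread of item parameters balanced across replications;
  sampling with replacement would occasionally produce degenerate designs
  with many identical items.
- **Seeding.** One master seed is split (`numpy` `SeedSequence`) into
  independent substreams for the design draw and the response draw; both
  are recorded in the dataset's JSON sidecar.

Responses are drawn directly from the implied Dirichlet/beta distributions
and stay on the continuous $(0,1)$ scale; an optional `discretize` flag
inverts the rescaling transforms and rounds back to the 0–100 integer grid
for exercising I/O paths. A separate sampler draws responses through the
latent mechanism the model assumes — three gamma variates with common scale
normalised to the simplex — and is used as an independent distributional
oracle for the direct sampler; the gamma scale cancels exactly and is never
represented at inference time.

What the generator does *not* emulate: round-number preference (empirical
response modes at 10, 20, …), boundary responses, response styles, or
multi-modal respondents. Passing recovery tests therefore show that the
estimator works when the model is true, not that the model fits any
particular empirical population.

## Estimation

All models are estimated with a package-local implementation of the
No-U-Turn sampler (multinomial variant, dual-averaging step-size
adaptation, windowed diagonal mass-matrix adaptation) operating on a fully
unconstrained parameter vector with analytic gradients. The gradients are
verified against central finite differences in the test-suite for every
model and prior preset, including the correlation coordinates of the joint
model.

Parameterisation choices:

- Person parameters have fixed group-level means (0) and SDs (1); they are
  never free parameters (identification).
- Item effects are *centered* ($\delta_j \sim \mathcal N(\mu_\delta,
  \sigma_\delta)$ sampled directly). At the study sizes this package
  targets every item sees every person, so item effects are data-dominated
  — the regime where the centered parameterisation mixes markedly better
  than the non-centred one (we measured roughly threefold higher effective
  sample size per second, with no divergent transitions in either
  parameterisation).
- Positive parameters ($\tau_j$, scale and positive-location
  hyperparameters, all $\alpha$) are sampled on the log scale with Jacobian
  terms. The truncated-normal prior on $\tau_j$ keeps its normalisation
  constant $\Phi(\mu_\tau/\sigma_\tau)$, which depends on sampled
  hyperparameters.
- In the joint model the person triplet $(\theta^B_i, \theta^D_i,
  \eta^D_i)$ is non-centred through the Cholesky factor of the correlation
  matrix, with the LKJ-Cholesky(1) prior expressed through the canonical
  partial-correlation transform of its three free coordinates.

Prior presets: `simulation` uses $\mathcal N(0,1.5)$ location hyperpriors
and $\Gamma(1.5, 1.5)$ (shape, rate) for scales, positive locations and
scaling parameters; `empirical` uses Student-t(3, 0, 2) (half-t for
positive parameters). The two presets are named, logged, and never mixed.
The joint model uses separate item-hyperparameters per sub-model, since the
two response formats are answered on different item sets; sharing them
would couple scales of different questionnaires for no substantive gain.

Sampler defaults: target acceptance 0.9, maximum tree depth 10. Preset
chain configurations are 4 chains × (500 warmup + 3500 sampling) for
simulation work and 4 × (4000 + 4000, thinning 2) for empirical work;
the package's own studies below use shorter chains (stated per study).
Two runs with the same seed, data, and configuration produce identical
draws.

### Diagnostics and summaries

Split-$\widehat R$, bulk- and tail-ESS come from `arviz`. A fit fails the
convergence report on any divergent transition (simulation context) or on
$\widehat R$ above the context threshold (1.05 simulation / 1.01
empirical); failed fits are excluded from recovery aggregation, mirroring
the exclusion rule of the recovery-study design. Point estimates are
posterior medians. HDIs use the shortest-window-over-sorted-draws method
with ties broken toward the lower bound. PSIS-LOO (elpd, $p_{loo}$,
Pareto-$\hat k$ flag counts at $\hat k > 0.7$) is computed by `arviz` from
stored pointwise log-likelihoods.

## Evaluation analytics

- **ADSM**: $|0.5 - (Y_L+Y_U)/2|$, the absolute deviance of the interval
  midpoint from the scale midpoint; reflection-invariant, in $[0, 0.5)$.
- **Manifest dependence**: Pearson correlation across persons of mean
  interval width with mean ADSM. Under the full simulation design this is
  strongly negative (≈ −0.74) purely as a bounded-scale artifact.
- **Latent dependence**: Pearson correlation of $|\theta|$ with $\eta$
  (true or recovered); near zero under the independent generating process.
- **Recovery metrics**: per parameter group, correlation with truth, mean
  signed bias, RMSE, and 95%-HDI coverage, aggregated over replications
  with normal-theory 95% confidence half-widths.
- **Posterior predictive checks**: marginal density overlays (Gaussian KDE,
  Silverman bandwidth, 512-point grid on $(0,1)$) for lower/upper bounds,
  interval location, width, and RS1 responses; and per-respondent
  inclusion-count functions (how many of a respondent's intervals contain
  each scale value).

Pearson correlations are used throughout.

## Problem sizes used by the packaged studies

The desk-scale analyses (manifest and true-latent dependence) regenerate
all 12 design cells at 25 replications each — 300 datasets — which takes
seconds. The model-based recovery study packaged in the test-suite is
scaled down to one condition (I=100, J=10) with 5 replications plus a
companion (I=100, J=20) study with 4 replications, each fitted with 2
chains of 500 + 1500 iterations; these sizes were chosen so the whole suite
runs comfortably on a single CPU while leaving the qualitative trends
(items ↓ person-RMSE, RMSE(θ) < RMSE(η), near-nominal θ coverage,
de-correlated recovered parameters) clearly resolvable. Chain length
matters more than replication count here: the posterior has a weakly
identified common location-shift mode (add a constant to all θ and δ;
only the person prior and μ_δ resist) with standard deviation of order
$I^{-1/2}$ that mixes slowly, and under-sampled chains leave shift noise
in per-replication RMSEs.

## Numerical choices and degenerate inputs

- Link-function exponents are clipped at $|30|$ in the user-facing shape
  functions (with a logged warning); inside the samplers, non-finite log
  densities are instead returned as $-\infty$ and treated as divergent
  leaves.
- Divergence threshold: energy error > 1000 (the usual NUTS convention).
- Simulated simplex responses are floored at $10^{-10}$ and renormalised:
  gamma draws with very small shape parameters can underflow to exactly
  zero, which would place a response on the simplex boundary outside the
  model's support.
- Dirichlet/beta evaluations reject boundary responses rather than nudging.
- Zero-variance person scores make the manifest correlation undefined; this
  is raised as an error, not returned as NaN.
- `recovery_metrics` treats a constant truth vector as having undefined
  correlation (NaN) while bias/RMSE remain defined.

## Known limitations

- No zero–one-inflation for boundary responses: data containing raw 0/100
  responses are handled by the interiorising transforms, not by a mixture.
- No frequentist estimation path.
- The expansion dimension is informationally weaker than the location
  dimension (single parameter vs. a tandem pair); recovery of $\eta$ and
  $\gamma$ is correspondingly worse, and $\eta$ and $\tau$ show a small
  negative bias at moderate sizes.
- The NUTS backend is single-threaded; chains run sequentially.
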