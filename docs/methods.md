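# Methods

## The model

`commnmix` fits a hierarchical community N-mixture model to repeat-visit
point-count data with imperfect detection and excess structural zeros. For
species *i* at point *j* in year *r*, with visits *v = 1..V*:

```
a_ijr ~ Bernoulli(psi_i)                    inclusion (zero-inflation)
M_ijr | a ~ Poisson(a_ijr * lambda_ijr)     latent abundance
y_ijrv ~ Binomial(M_ijr, phi_ijrv)          observed counts

log(lambda_ijr)   = beta0_i + beta_i . x_jr + gamma_t(j)
logit(phi_ijrv)   = alpha0_i + alpha_i . v_jrv
```

`x_jr` holds standardized vegetation covariates (grass %, woody %, VOR2 %,
basal area m²/ha) plus a raw 0/1 treatment flag; `v_jrv` holds standardized
day-of-season, its square, wind, and disturbance. Species intercepts and
slopes are exchangeable Normal draws around community hyper-means
(`beta0_i ~ N(mu_beta0, sigma_beta0^2)`, likewise every slope and the
detection terms), which is what lets rarely detected species borrow
strength from the community. `gamma_t` is a site random effect shared
across species. Year and observer are deliberately not model terms.

### Exact marginalization

Rather than Gibbs-sampling the latent `a` and `M` (the classic BUGS/JAGS
route), both are summed out analytically, which gives identical posteriors
for the continuous parameters with far better mixing:

- a cell whose visit counts are all zero has the closed form
  `(1 - psi) + psi * exp(-lambda * (1 - q))` with
  `q = prod_v (1 - phi_v)` — exact for any lambda, no truncation;
- a cell with observations sums
  `psi * sum_{M >= max(y)}^{K} Pois(M; lambda) prod_v Bin(y_v; M, phi_v)`.

The truncation bound `K` is adaptive. The scalar reference implementation
extends the sum until the log-likelihood changes by less than 1e-12 (so any
further increase of `K` moves it by well under 1e-8). The vectorized
implementation buckets observed cells by their largest count and gives each
bucket a grid sized for Poisson rates up to 12x that count (detection rates
down to ~0.08); proposals beyond that cap evaluate to -inf, i.e. are
rejected. Visit-level binomial coefficients are data constants and
precomputed once.

### Priors

- Hyper-means (all fixed effects): Normal(0, precision 0.001).
- Hyper standard deviations and the site-effect scale: half-Normal(0, 2).
  The source analysis stated priors only for the fixed effects; a weakly
  informative half-Normal is the standard choice and is configurable.
- Zero-inflation `psi_i`: Beta(1, 1) per species (also unstated upstream).

The inclusion probability is treated as a species-level quantity shared
across sites. Its subscripting could also be read as species-by-site, but a
single value per species is what the suite-level reporting implies, and a
site-varying version would add 18 x 12 weakly identified parameters.

## Inference

No probabilistic-programming backend is assumed; the sampler is an adaptive
Metropolis-within-Gibbs scheme written directly on the marginalized
likelihood (`commnmix.mcmc`):

- **Species blocks.** Abundance coefficients `(beta0_i, beta_i)` and
  detection coefficients `(alpha0_i, alpha_i)` get multivariate random-walk
  proposals with per-species empirical-covariance adaptation (Haario-style,
  target acceptance 0.25). Species are conditionally independent given the
  hyperparameters, so all proposals are evaluated in one vectorized pass
  and accepted per species.
- **Intercept ridge block.** Counts identify `lambda * phi` and `psi`
  mostly jointly, producing posterior ridges between `beta0_i`, `alpha0_i`
  and `logit(psi_i)`. A dedicated 3-dimensional block per species learns
  that ridge through its adapted covariance.
- **Site effects** are proposed for all sites at once and accepted per site
  (sites partition the cells).
- **Translation moves.** Shifting every species intercept and its
  hyper-mean up while shifting all site effects down leaves every linear
  predictor unchanged; the analogous move pairs the treatment coefficients
  with the treated sites' effects. Both are Metropolis steps on the prior
  alone and decorrelate hyper-means from site effects.
- **Recentering.** A joint move shifts each hyper-mean together with all
  its species coefficients, so hyper-means travel at the likelihood's pace
  rather than diffusing through the much tighter species-level
  conditionals (this is also what lets the sampler reproduce the vague
  prior when run on empty data).
- **Rotating column moves.** Each iteration visits two coefficient columns
  with (a) a joint (hyper-mean shift, spread scale) proposal in which the
  species-prior ratio cancels against the rescaling Jacobian — an
  ancillarity-sufficiency style update — and (b) scalar random walks on
  that column's species values, accepted per species. The scalar step is
  capped at 2.5x the column's current hyper-sd so species values keep
  re-aligning deep in the sigma -> 0 funnel instead of freezing.
- **Non-centered slice draws for hyper-sds.** Every fourth iteration one
  column's log hyper-sd gets a slice draw holding the standardized
  residuals fixed (conditional: likelihood at mu + sigma z times the
  half-Normal prior). A slice draw can cross the entire sigma range at
  once, which is what frees chains from funnel tips that random-walk scale
  moves escape only diffusively.
- **Hyper-means** are conjugate Gibbs draws; hyper-sds are additionally
  slice-sampled from their centered conditionals, which depend only on the
  residual sums of squares (no likelihood term).

All adaptation happens during burn-in only. Chains are seeded
independently from the global seed; a fixed seed reproduces every draw
bit-for-bit. The marginal likelihood itself is evaluated by a numba
kernel: one pass over all species x cells, closed form for all-zero cells
and an early-terminated (the summand is unimodal in M) truncated sum for
observed cells, at roughly a quarter of a millisecond per full evaluation
for the one-season study.

**Budget.** The defaults run 3 chains. The desk-scale budget used by the
tests (3,600 iterations, 40% burn-in, thin 1) fits the one-season
12 x 150 x 3 dataset in under a minute on one CPU with all monitored
R-hat < 1.1; the original 3 x 200,000 / 100,000 / thin-5 budget remains
reachable through `McmcConfig`.

**Convergence** is assessed with the classic Gelman-Rubin potential scale
reduction (between/within chain variance; threshold 1.1) on a monitored set
defaulting to the community hyperparameters. Chains with zero within-chain
variance are flagged degenerate rather than crashing. Summaries are
pooled-chain means with equal-tailed 95% credible intervals (empirical
quantiles, linear interpolation); a coefficient is flagged informative when
its interval excludes 0.

## Derived quantities

- **Detection probability P_d** per species is the inverse-logit of the
  detection intercept: detection covariates are centered, so the intercept
  is detection at average survey conditions. Suite and community values are
  per-draw unweighted means over member species, so their credible
  intervals propagate species-level uncertainty.
- **Zero-inflation** summaries are the same construction over `psi` draws.
- **z-matrix.** Per posterior draw, a species is present at a point iff its
  latent abundance is positive in at least one year. Cells with any
  observed count force presence; all-zero cells sample absence from the
  exact conditional `P(M = 0 | y = 0) = [(1-psi) + psi e^{-lambda}] /
  [(1-psi) + psi e^{-lambda(1-q)}]`, multiplied across years. By default
  250 evenly spaced draws are used.
- **Jaccard co-occurrence** `J_ij = |A_i ∩ A_j| / |A_i ∪ A_j|` over
  occupied point sets, computed per draw per species pair (66 pairs for 12
  species) and summarized with 95% CrIs. Draws in which both species are
  absent everywhere leave J undefined; such draws are dropped from that
  pair's summary and counted in `n_dropped`.
- **Suite-level coefficients** are per-draw means of member species'
  coefficients; the community row reports the hyper-mean's own draws.
- **Natural-scale effects.** `rescale_effect` converts a standardized
  coefficient into birds per plot for a raw covariate shift:
  `lambda_baseline * (exp(beta * delta / sd) - 1)` per draw. The plot area
  and baseline are explicit inputs because translations like "birds per 26
  m²/ha thinning" depend on them.

## The synthetic world

The generator (`commnmix.synth`) emulates the study design: 18 sites,
near-equally allocated 150 points (six 9-point and twelve 8-point sites,
greedily split into treatment/control halves of exactly 75 points each),
3 visits per season, 4 survey years, 12 species in the Forested Upland /
Scrub-Shrub / Grassland suites.

Vegetation covariates are truncated-normal draws whose location, scale, and
bounds equal the per-group summary statistics of the managed vs unmanaged
regimes (e.g. basal area: control 28.89 ± 9.83 on [3.44, 65.04] m²/ha,
treatment 9.45 ± 8.04 on [0, 34.05]). Only mean/sd/range are known, and the
truncated normal is the simplest family matching all three. Two caveats:
the grass/control regime (0.28 ± 1.64 on [0, 15]) is strongly truncated, so
its realized mean exceeds the location parameter; and pooling the two
groups induces a moderate (|r| ≈ 0.5) grass-woody correlation through the
group contrast — a real feature of such designs, still below the 0.7
screening threshold. Draws are independent per point x year (emulating
remeasurement variation); no year dynamics, spatial autocorrelation, or
distance-dependent detection are simulated, and counts are pooled over
distance classes. Optional redundant covariates (forbs, bare, litter,
VOR025, VOR1, canopy) are generated with planted |r| > 0.7 against their
retained partners to exercise the collinearity screen.

Visit dates are uniform within consecutive thirds of a 16 May - 10 Aug
(86-day) window, mimicking ~3-week revisit intervals; wind is uniform on
[0, 15) km/h (surveys above that are not conducted) and disturbance an
ordinal 0-4 score.

Default community hyperparameters (used by tests and the recovery study):
baseline abundance ~2 birds per plot (`mu_beta0 = 0.7`, sd 0.3), moderate
vegetation effects (grass +0.3, woody -0.2, VOR2 +0.2, basal **-0.4**,
treatment +0.4; sd 0.3), per-visit detection ~0.18 (`mu_alpha0 = -1.5`, sd
0.25) with date +0.2, date² -0.15, wind -0.2, disturbance -0.1 (sd 0.2),
inclusion probability 0.6, site-effect sd 0.2. A green recovery test
establishes calibration *under this stated world* — correct likelihood,
sampler, and summaries — not that field data of this size would pin down
every parameter.

## Pre-modelling steps

`standardize` centers to mean 0 / sample sd 1 (divisor n-1) and stores the
constants for exact back-transformation; constant covariates are rejected.
The standardization population pools all point x year rows (one design
matrix). The date-squared term is the square of the standardized date.

`correlation_screen` retains covariates greedily in the priority order
basal > grass > woody > VOR2 > rest (basal area being the routine forestry
measurement), excluding any candidate whose Pearson |r| with an
already-retained covariate exceeds 0.7, and records the triggering partner.

`compare_groups` is Welch's unequal-variance t-test with honest
Welch-Satterthwaite degrees of freedom. (Group comparisons on all 1,800
surveys treated as independent would overstate df; the pipeline reports the
df the data support.)

## Numerical choices and edge cases

- Detection rates are clipped to [1e-12, 1 - 1e-12] inside the likelihood;
  `psi = 0` and `psi = 1` are handled exactly in the scalar reference.
- `K` caps at 300 by default (configurable); a cell whose largest count
  needs more raises rather than silently truncating.
- Initialization: hyper-means 0, scales 1, `psi` at each species' observed
  proportion of non-zero cells, coefficients at the hyper-means — all
  jittered per chain; a non-finite start is re-jittered up to 10 times.
- Undefined Jaccard pairs and degenerate R-hat are flagged, never raised.
- Empty data (zero cells) is valid: the likelihood is 0 everywhere and the
  sampler reproduces the prior (tested).

## Known limitations

- The sampler is random-walk based; for much larger communities or many
  years a gradient-based sampler on the same marginalized likelihood would
  scale better.
- Suite summaries are derived means over species draws, not separate suite
  hyperpriors.
- The z-matrix presence definition (latent abundance positive in any year
  at a point) is one reasonable reading; point x year occupancy would give
  systematically lower co-occurrence.
- No model comparison (WAIC/DIC), distance sampling, or data augmentation
  for unobserved species.
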