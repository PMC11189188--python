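# commnmix

Hierarchical community N-mixture modelling of repeat-visit point counts,
with zero inflation, imperfect detection, community hyperpriors, and
posterior Jaccard co-occurrence.

## The problem

Point-count surveys for breeding birds record, per species, how many
individuals an observer detects in a fixed-radius plot during a timed
visit. Raw counts confound abundance with detection: a bird present in the
plot is often not seen or heard, and many plots that look empty are
structurally unsuitable rather than unluckily surveyed. When the question
is how forest structure (groundcover, midstory obstruction, canopy basal
area, active management) shapes a whole community of priority species —
many of them rare — species cannot be analyzed one at a time without
losing most of the information.

`commnmix` implements the standard answer for this design: a zero-inflated
Poisson–binomial N-mixture model with community-level hyperpriors. For
species *i*, point *j*, year *r*, visit *v*:

```
a_ijr ~ Bernoulli(psi_i)                  structural suitability
M_ijr | a ~ Poisson(a_ijr · lambda_ijr)   latent abundance
y_ijrv ~ Binomial(M_ijr, phi_ijrv)        observed counts

log(lambda_ijr) = beta0_i + beta_i · x_jr + gamma_site
logit(phi_ijrv) = alpha0_i + alpha_i · v_jrv
beta0_i ~ N(mu_beta0, sigma_beta0²)   (and likewise every coefficient)
```

Species-level coefficients are drawn around community means, so sparsely
detected species borrow strength from the rest of the community. The
latent `a` and `M` are marginalized exactly (closed form for all-zero
cells, adaptively truncated sums otherwise), and the posterior is sampled
with a self-contained adaptive Metropolis-within-Gibbs sampler — no
probabilistic-programming backend required. From the posterior the package
derives detection probability `P_d`, zero-inflation `phi`, suite-level
coefficients, latent presence/absence z-matrices, and pairwise Jaccard
co-occurrence indices `J_ij = |A_i ∩ A_j| / |A_i ∪ A_j|` with full
uncertainty propagation. A synthetic-data generator emulating a
treatment/control forest-stewardship study (18 sites, 150 points, 3 visits
per season, 4 years, 12 species in 3 habitat suites) makes every stage
testable without field data.

See `docs/methods.md` for the model, priors, sampler moves, and the
synthetic world's assumptions.

## Worked example

```python
import commnmix as cx

design = cx.SurveyDesign(n_years=1)           # one season, 150 points
cov    = cx.generate_covariates(design, rng_seed=1)
params = cx.draw_species_params(cx.default_hyperparams(), design, rng_seed=2)
counts = cx.simulate_counts(params, cov, design, rng_seed=3)

data  = cx.ModelData.from_tables(counts, cov)
draws = cx.run_mcmc(data, config=cx.McmcConfig(
    n_chains=3, n_iterations=2400, n_burnin=1200, thin=1, seed=7))
print(cx.summarize(draws, ["mu_beta[basal]", "mu_alpha0"]).round(3))
```

prints

```
                 mean  lower  upper  significant   rhat
parameter
mu_beta[basal] -0.294 -0.491 -0.106         True  1.011
mu_alpha0      -1.562 -1.839 -1.305         True  1.071
```

The community basal-area effect is recovered as clearly negative (truth
−0.4: denser canopy, fewer birds) with its 95% credible interval excluding
0, and the detection intercept −1.56 (truth −1.5) corresponds to a
per-visit detection probability of about 0.18. `rhat` < 1.1 indicates the
three chains agree.

The numbered drivers under `analysis/` run the same workflow as a
narrative: `01_simulate_survey.py` (full 4-year design),
`02_covariate_prep.py` (standardization, |r| > 0.7 collinearity screen,
treatment-vs-control Welch tests), `03_fit_community_model.py`,
`04_derived_quantities.py` (P_d, zero-inflation, suites, Jaccard,
natural-scale basal effect), `05_parameter_recovery.py` (coverage study).
Each writes its tables under `results/analysis/`. The same stages are also
exposed as a CLI: `commnmix simulate|prep|fit|summarize|derive|run`.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end result from scratch: it simulates the
full study design (1,800 surveys × 12 species), standardizes and screens
covariates, fits the community model with 3 MCMC chains, checks
convergence, and derives the detection, zero-inflation, suite, and Jaccard
tables (written next to the JSON under `results/`).
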