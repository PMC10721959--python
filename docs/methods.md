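# Methods

## The model

`fireabund` implements hierarchical multi-species (community) abundance
models for pollinator counts from nested post-fire surveys. Counts
N_ijk of species *i* at plot *j* on visit *k* are negative binomial with
a species- and cell-specific mean and a dispersion *r* shared by all
species of a community model:

    N_ijk ~ NegBin(lambda_ijk, r),       Var = lambda + lambda^2 / r

    log lambda_ijk = beta_0i
                   + beta_1i * Snowmelt_jk     (days since snowmelt)
                   + beta_2i * Richness_jk     (floral richness)
                   + beta_3i * Inflor_jk       (floral abundance)
                   + beta_4i * Elevation_j
                   + beta_5i * Year_jk         (indicator, ref. 2016)
                   + beta_6i * Burn_j          (RdNBR)
                   + beta_7i * [upland] Burn_j^2
                   + beta_8i * [upland] Burn_j
                   + beta_hab,i * [upland]
                   + eps_site(j)

Every species-level coefficient is drawn from a community
hyperdistribution, `beta_ci ~ Normal(mu_c, sigma_c)`, which shares
information across species and makes rare species estimable; `eps_site ~
Normal(0, sigma_site)` absorbs the nesting of plots in sites and the
repeated sampling of plots. The quadratic burn term is structurally
zero in meadows, where intermediate severities are not represented; the
negative binomial tends to the Poisson as `r -> inf`.

Single-species variants (one per butterfly family; one for all
hummingbirds) use the same linear predictor with independent
`Normal(0, 10)` priors in place of the community layer. The butterfly
variant drops the year and quadratic-burn columns (single-season,
two-severity-class sampling); the hummingbird variant keeps everything.

A note on the habitat main effect: the model includes an explicit
upland-indicator column (`beta_hab`), so the habitat contrast is carried
by the categorical term and the floral covariates measure within-habitat
deviations. The flag `ModelFlags.include_habitat_main` can remove it.

## Priors

Hyperpriors are vague and configurable (`PriorConfig`):

| parameter    | prior            | rationale                               |
|--------------|------------------|-----------------------------------------|
| mu_c         | Normal(0, 10)    | flat over plausible log-scale effects    |
| sigma_c      | Uniform(0, 10)   | standard weakly-informative SD prior     |
| sigma_site   | Uniform(0, 10)   | same                                     |
| r            | Gamma(0.1, 0.1)  | diffuse over dispersion scales           |
| beta (non-hierarchical) | Normal(0, 10) | single-species variants        |

## Covariate construction

* **Frequent-plant filter** — floral covariates are computed from plants
  that received at least 10 recorded flower visits (`min_visits`
  configurable). Rarely- and never-visited plants carry no information
  about food available to the surveyed pollinators.
* **Floral abundance** — summed open inflorescences of frequent plants
  over a plot-visit's eight 1-m² quadrats. **Floral richness** — number
  of distinct frequent plants in bloom across the union of those
  quadrats (a plant counts wherever any quadrat shows > 0 open
  inflorescences).
* **Species inclusion** — community models keep species detected in at
  least three distinct plots.
* **Standardization** — all continuous covariates are centred and
  scaled to sample SD 1 (n−1 denominator). Floral richness and
  abundance are standardized *within habitat*, so their habitat-level
  baseline is carried by the categorical habitat term. Burn severity is
  standardized globally before squaring; the quadratic column is the
  square of the standardized value.
* **Double sampling periods** — visits surveyed in two consecutive
  periods are pooled by element-wise summation (no detectability
  submodel; see Non-goals).
* **Missing plot-visits** — the survey design is unbalanced across
  years; unsurveyed cells are masked out of the likelihood, never
  imputed.
* Snowmelt reference dates: 2016-06-06 and 2017-06-18.

## Posterior sampling

The sampler (`fireabund.sampler.fit`) is a component-wise adaptive
random-walk Metropolis-within-Gibbs scheme, compiled with numba:

* species coefficients: scalar random-walk Metropolis. When only the
  mean changes, the log-gamma terms of the NB pmf cancel from the MH
  ratio, so a coefficient update costs only logs/exps over that
  species' cells;
* per-species joint Metropolis proposals from the empirical covariance
  of the chain so far (scaled 2.38²/p), handling correlated design
  columns;
* a likelihood-invariant translation move exchanging mass between the
  species intercepts and the site effects (these enter the likelihood
  only through their sum), and a community "column translation" that
  shifts `mu_c` and all `beta_ci` together, whose species-prior terms
  cancel — both target otherwise slow ridge directions of the
  hierarchy;
* pairwise coefficient exchanges along structurally correlated column
  pairs (upland indicator vs intercept; burn-by-upland interaction vs
  burn main effect): the paired columns coincide on upland rows, so
  shifting one coefficient up and the other down changes the likelihood
  only on meadow rows;
* community hyper-means: conjugate Normal Gibbs draws;
* `sigma_c`, `sigma_site`, `r`: log-scale random-walk Metropolis with
  the transform Jacobian, plus a non-centered "interweaving" rescaling
  of `sigma_site` that moves all site effects jointly with their SD,
  breaking the hierarchical funnel;
* all proposal scales adapt by Robbins-Monro (targets 0.44 scalar /
  0.234 joint) during burn-in only and are frozen afterwards, so the
  retained chain is a valid Markov chain on the posterior.

Defaults mirror the reporting convention of three chains of 100,000
iterations with 50,000 burn-in and no thinning; every entry is
configurable, and the chains are bit-reproducible given (data, config,
seed). Initialization draws coefficients and site effects from
small-variance Normals about 0, sets SD parameters at their prior
middles and r = 1, and retries until the log-posterior is finite.
The cached NB means are refreshed from scratch every 500 iterations to
kill accumulated multiplicative floating-point drift.

## Diagnostics and reporting

* **Convergence** — classic (non-split) Gelman-Rubin
  `Rhat = sqrt(((n-1)/n W + B/n)/W)`; `Rhat <= 1.1` is taken as
  convergence. A split-chain variant is available behind a flag.
* **Summaries** — posterior mean, SD, and the 2.5th/97.5th percentiles
  (type-7 linear interpolation, so summaries are bit-reproducible) as
  the 95% credible interval; a coefficient is *significant* when the
  interval excludes zero.
* **Goodness-of-fit** — posterior-predictive Bayesian p-values per
  species and for the community (discrepancies summed over species),
  with the Freeman-Tukey discrepancy `T = sum (sqrt(y) - sqrt(lam))^2`
  by default (chi-square available). Ties count as "replicate >=
  observed". Values in (.1, .9) indicate adequate fit.
* **Recovery scoring** — `parameter_recovery` reports bias, RMSE and
  95%-interval coverage of any parameter set across replicate fits.

## Synthetic surveys

The generator (`fireabund.synthetic`) emulates the survey structure the
model assumes, with every default chosen to match the real design:
36 upland + 6 meadow sites; 3–5 plots per site, each site a homogeneous
habitat/severity patch (plot RdNBR = site value + Normal(0, 40) noise);
3 visits in year one and 2 in year two; 75% of upland sites surveyed in
a single year (meadows always in both), which exercises the missing-cell
mask; elevation uniform on 1300–1800 m. Upland site severities spread
across the unburned/moderate/high components (means 30/450/950 RdNBR,
SDs 60/120/120); meadow sites draw from the same components with
weights (0.45, 0.10, 0.45), leaving intermediate severities
under-represented as in the field.

Floral covariates arise from a latent Gaussian score with configurable
correlation to standardized burn severity (default −0.3): richness is a
binomial thinning of the 30-plant frequent pool through a logistic link
with habitat-specific baselines (meadows richer), and abundance is
rounded log-normal with habitat-specific location, floored at one
inflorescence per blooming plant. This mechanism is the package's own
construction: it reproduces the habitat/burn correlation structure the
analysis must cope with, but no claim is made that it matches the joint
field distribution — passing recovery tests therefore demonstrates
correctness of the inference machinery under the assumed model, not
robustness to real-data misspecification (no phenology curves, no
spatial autocorrelation beyond the site effect, no inter-species
interaction, no detection process).

Species coefficients are drawn from the configured hyperdistributions.
Demonstration truth values echo the qualitative field pattern (meadow
habitat positive, richness positive, upland quadratic burn response)
but are synthetic, not estimates. Counts come from the same
`simulate_counts` routine used for posterior-predictive replication.

## Validation and problem sizes

The test suite validates the chain against a fine-grid numerical
posterior (KS distance < 0.02 on a single-species intercept-only
model), the likelihood against triple-loop and scipy references
(1e-10), the NB pmf against normalization and the Poisson limit, and
prior-only sampling against the prior moments. Full-pipeline checks run
at reduced scale chosen to keep the suite fast while leaving the model
well identified:

* convergence: 7 species, 20 sites × 4 plots × 3 visits; 3 chains,
  4,000 iterations (2,000 burn-in);
* goodness-of-fit calibration: 20 replicates at that scale (community
  p-value inside (.1, .9) in at least 90% of them);
* recovery/coverage: 50 replicates of 20 species, 30 sites × 4 plots ×
  3 visits, 2 chains of 3,000 iterations (1,500 burn-in); hyper-mean
  bias within ±0.1 and interval coverage inside the 99% binomial band
  around 0.95.

`scripts/acceptance.py` recomputes the convergence maximum, a
correctly-specified community p-value, and the richness hyper-mean
coverage percentage from scratch at these scales.

## Known limitations

* The Metropolis-within-Gibbs engine is general but not gradient-based;
  very large communities (hundreds of species) would benefit from HMC.
* A single shared dispersion r per model is assumed, as in the
  analysis; per-species dispersion is not implemented.
* The Bayesian p-value's discrepancy function is a default choice
  (Freeman-Tukey); conclusions near the fit-band edges can depend on it.
* Site effects are exchangeable; no spatial covariance between sites.
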