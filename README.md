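# fireabund

Hierarchical Bayesian multi-species abundance modelling for pollinator
counts under burn severity, habitat and floral-resource covariates.

Wildfire reshapes pollinator habitat, but its effect depends on burn
severity and habitat type: meadows and closed-canopy ("upland") conifer
forest respond very differently, and floral resources mediate both.
`fireabund` is a self-contained Python implementation of the community
abundance analysis used to study such questions: it turns raw nested
survey tables (species counts per plot visit, quadrat floral records,
plot burn severity and elevation) into a standardized design, fits a
hierarchical negative-binomial community model by MCMC, and reports
convergence, coefficient summaries and posterior-predictive
goodness-of-fit. A synthetic survey generator with the same nested
structure makes the whole pipeline testable end to end — including
parameter recovery and credible-interval calibration — without any
archived field data.

## The model

Counts N_ijk of species *i* at plot *j* on visit *k*:

    N_ijk ~ NegBin(lambda_ijk, r)        Var = lambda + lambda^2/r

    log lambda_ijk = beta_0i + beta_1i Snowmelt_jk + beta_2i Richness_jk
                   + beta_3i Inflor_jk + beta_4i Elevation_j
                   + beta_5i Year_jk + beta_6i Burn_j
                   + beta_7i [upland] Burn_j^2 + beta_8i [upland] Burn_j
                   + beta_hab,i [upland] + eps_site(j)

    beta_ci ~ Normal(mu_c, sigma_c)      (community hyperdistribution)
    eps_s   ~ Normal(0, sigma_site)      (site random effect)

The community layer shares information across species so that rare
species remain estimable; the dispersion r is shared within a model;
the quadratic burn term exists only in upland habitat. Coefficients are
reported as posterior means with 95% credible intervals (2.5th–97.5th
percentiles); chains are declared converged at Gelman–Rubin Rhat ≤ 1.1,
and fit is checked with posterior-predictive Bayesian p-values
(adequate inside .1–.9). See `docs/methods.md` for the full account.

## Worked example

```bash
python examples/simulate_and_fit.py
```

simulates a 7-species community (20 sites × 4 plots × 3 visits), fits
it with three chains of 4,000 iterations, and prints:

```
simulated 7 species x 240 plot-visits (20 sites); total detections 5377
max Rhat = 1.037 (<= 1.1 indicates convergence)

community hyper-means (posterior mean [95% BCI], * = interval excludes 0):
       intercept: +1.14 [+0.40, +1.87]*   (generating value +1.00)
        snowmelt: -0.07 [-0.42, +0.27]    (generating value -0.20)
        richness: +0.23 [-0.15, +0.61]    (generating value +0.40)
          inflor: +0.27 [-0.16, +0.72]    (generating value +0.05)
       elevation: -0.17 [-0.48, +0.13]    (generating value -0.10)
            burn: -0.56 [-1.04, -0.08]*   (generating value -0.30)
    burn2_upland: -0.05 [-0.43, +0.31]    (generating value -0.30)
   burn_x_upland: +0.83 [+0.32, +1.36]*   (generating value +0.40)
          upland: -0.84 [-1.42, -0.31]*   (generating value -0.80)

community Bayesian p-value = 0.610 (values in (.1, .9) indicate adequate fit)
```

Every interval here either covers its generating value or misses it the
way a 95% interval occasionally should; the p-value sits comfortably in
the fit band because the data really do come from the fitted model.
`examples/preprocessing_pipeline.py` walks the raw-CSV route (plant
filters, within-habitat standardization, design assembly) and
`examples/recovery_study.py` runs a small bias/coverage study.

The same stages are scriptable from a shell:

```bash
fireabund simulate   --config config.yaml --out data/
fireabund preprocess --config config.yaml --data data/ --out prep/
fireabund fit        --config config.yaml --data prep/model_data.json --out chains/
fireabund diagnose   --config config.yaml --chains-dir chains/ \
                     --data prep/model_data.json --out report/
fireabund recover    --config config.yaml --replicates 5 --out recovery/
```

## Layout

```
src/fireabund/
  preprocessing.py   filters, floral metrics, standardization, design builder
  model_core.py      NB likelihood, priors, forward simulator
  sampler.py         adaptive Metropolis-within-Gibbs (+ numba kernel)
  diagnostics.py     Rhat, summaries, Bayesian p-values, recovery scoring
  synthetic.py       nested survey generator with known truth
  io.py              CSV/JSON interchange formats
  cli.py             the pipeline commands shown above
```
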