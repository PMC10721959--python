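# Pipeline configuration

All `fireabund` subcommands accept `--config <file.yaml>`; `--seed`
overrides the config seed, and `--chains/--iterations/--burnin` override
the corresponding MCMC entries on `fit`. Unknown keys are rejected with
an error naming the offending key. Every key is optional; the defaults
are the dataclass defaults of `DesignConfig`, `McmcConfig` and
`PriorConfig`.

```yaml
seed: 1                       # master seed for the invoked stage

design:                       # synthetic-study generator (simulate, recover)
  n_upland_sites: 36
  n_meadow_sites: 6
  plots_per_site: [3, 5]      # inclusive range
  visits_per_year: [3, 2]     # one entry per year
  years: [2016, 2017]
  upland_single_year_frac: 0.75
  meadow_severity_weights: [0.45, 0.10, 0.45]
  n_frequent_plants: 30
  floral_burn_rho: -0.3
  n_species: 20
  r: 2.0
  sigma_site: 0.3
  flags:                      # model variant (also a top-level key for
    include_year: true        # preprocess, where no design is needed)
    include_quadratic: true
    include_habitat_main: true
    hierarchical: true

mcmc:                         # fit, recover
  n_chains: 3
  n_iterations: 100000
  n_burnin: 50000
  thin: 1

prior:                        # fit, recover
  mu_sd: 10.0
  sigma_upper: 10.0
  sigma_site_upper: 10.0
  r_shape: 0.1
  r_rate: 0.1
  beta_sd: 10.0

gof:                          # diagnose
  n_draws: 500
  discrepancy: freeman_tukey  # or chi_square

recover:
  n_replicates: 5
```

Stage artifacts: `simulate` writes `counts.csv`, `plots.csv`,
`visits.csv`, `quadrats.csv`, `visitation.csv`, `truth.json`;
`preprocess` writes `model_data.json`; `fit` writes `chain<k>.csv` and
`chains_manifest.json`; `diagnose` writes `fit_report.csv` and
`gof.json`; `recover` writes `recovery.csv`. Every output directory
also receives a `manifest.json` with the subcommand, seed, config and
input digests, package version and timestamp.
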