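"""Small parameter-recovery study: simulate, fit, score.

Runs five simulate-and-fit replicates at a reduced scale and reports
bias, RMSE and 95%-interval coverage for the community hyper-means —
the check that the whole pipeline estimates what the generator put in.
(The full validation uses 50 replicates; see tests/test_acceptance.py.)
"""

from fireabund import (DesignConfig, McmcConfig, fit, fit_report,
                       generate_dataset, parameter_recovery)

N_REPLICATES = 5
reports, truth = [], None
for rep in range(N_REPLICATES):
    cfg = DesignConfig.reduced(n_species=10, n_sites=15, plots_per_site=4,
                               n_visits=3)
    study = generate_dataset(cfg, seed=rep + 1)
    chains = fit(study.model_data,
                 mcmc=McmcConfig(n_chains=2, n_iterations=2500,
                                 n_burnin=1250, seed=rep + 1))
    reports.append(fit_report(chains, include_rhat=False))
    if truth is None:
        truth = {k: v for k, v in study.truth.items() if k.startswith("mu[")}
    print(f"replicate {rep + 1}/{N_REPLICATES} fitted")

table = parameter_recovery(truth, reports)
print("\nhyper-mean recovery over", N_REPLICATES, "replicates:")
print(table.to_string(float_format=lambda v: f"{v: .3f}"))
print("\nbias near 0 and coverage near 0.95 indicate a calibrated "
      "pipeline; with only 5 replicates expect coverage of 0.8 or 1.0.")
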