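"""Posterior sampling for the hierarchical abundance model.

The scheme is component-wise adaptive random-walk Metropolis within
Gibbs: community hyper-means have conjugate Normal full conditionals and
are Gibbs-updated; everything else moves by random-walk Metropolis
(SD-type parameters and the dispersion on the log scale). Proposal
scales adapt toward 0.44 acceptance during burn-in and are frozen after,
so the post-burn-in chain is a valid Markov chain on the posterior.

Default chain settings follow the study convention of three chains of
100,000 iterations with 50,000 burn-in; tests and the bundled replicate
studies use reduced counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ._kernels import run_chain
from .errors import ContractError, InitializationError
from .model_core import (CommunityHyperparameters, ModelData, PriorConfig,
                         SiteEffects, SpeciesCoefficients, log_posterior)

__all__ = ["McmcConfig", "PosteriorChains", "initialize", "fit"]


@dataclass(frozen=True)
class McmcConfig:
    """Chain-run settings (defaults mirror the full-scale analysis)."""

    n_chains: int = 3
    n_iterations: int = 100_000
    n_burnin: int = 50_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ContractError("n_burnin must be < n_iterations")
        if self.n_chains < 1:
            raise ContractError("need at least one chain")
        if self.thin < 1:
            raise ContractError("thin must be >= 1")


@dataclass
class PosteriorChains:
    """Post-burn-in posterior draws for every monitored parameter.

    ``draws`` is (n_chains, n_kept, n_params); ``names`` labels the last
    axis. ``acceptance`` holds post-burn-in acceptance rates per chain and
    parameter (1.0 for Gibbs-updated parameters).
    """

    names: list[str]
    draws: np.ndarray
    config: McmcConfig
    acceptance: np.ndarray
    meta: dict = field(default_factory=dict)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def get(self, name: str) -> np.ndarray:
        """(n_chains, n_kept) draws of one parameter."""
        return self.draws[:, :, self.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated, one flat vector."""
        return self.get(name).ravel()

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]


def parameter_names(data: ModelData, hierarchical: bool) -> list[str]:
    names = [
        f"beta[{sp}][{col}]"
        for sp in data.species_ids
        for col in data.column_names
    ]
    if hierarchical:
        names += [f"mu[{col}]" for col in data.column_names]
        names += [f"sigma[{col}]" for col in data.column_names]
    names += ["sigma_site", "r"]
    names += [f"eps[{s}]" for s in (data.site_ids
                                    or [str(i) for i in range(data.n_sites)])]
    return names


def initialize(data: ModelData, prior: PriorConfig, seed,
               fixed_r: float | None = None,
               max_retries: int = 20) -> dict:
    """Finite-log-posterior starting state: coefficients and site effects
    from small-variance draws about 0, SDs at their prior middles, r = 1."""
    rng = np.random.default_rng(seed)
    hierarchical = data.flags.hierarchical
    for _ in range(max_retries):
        state = {
            "beta": rng.normal(0.0, 0.1, size=(data.n_species, data.n_coef)),
            "eps": rng.normal(0.0, 0.1, size=data.n_sites),
            "mu": rng.normal(0.0, 0.1, size=data.n_coef),
            "sigma": np.full(data.n_coef, prior.sigma_upper / 2.0),
            "sigma_site": prior.sigma_site_upper / 2.0,
            "r": 1.0 if fixed_r is None else float(fixed_r),
        }
        hyper = CommunityHyperparameters(
            mu_beta=state["mu"], sigma_beta=state["sigma"],
            r=state["r"], sigma_site=state["sigma_site"],
        )
        lp = log_posterior(
            SpeciesCoefficients(state["beta"]), SiteEffects(state["eps"]),
            hyper, data, prior, hierarchical=hierarchical,
        )
        if np.isfinite(lp):
            return state
    raise InitializationError(
        f"no finite starting state found in {max_retries} attempts"
    )


def _site_csr(site_index: np.ndarray, n_sites: int):
    order = np.argsort(site_index, kind="stable").astype(np.int64)
    counts = np.bincount(site_index, minlength=n_sites)
    ptr = np.zeros(n_sites + 1, dtype=np.int64)
    np.cumsum(counts, out=ptr[1:])
    return ptr, order


def fit(data: ModelData, prior: PriorConfig = PriorConfig(),
        mcmc: McmcConfig = McmcConfig(), *,
        fixed_r: float | None = None,
        likelihood_on: bool = True,
        site_effects: bool = True,
        initial_states: Mapping[int, dict] | None = None) -> PosteriorChains:
    """Run the adaptive Metropolis-within-Gibbs sampler.

    Deterministic given (data, prior, mcmc.seed). ``fixed_r`` pins the
    dispersion (useful for oracle comparisons); ``likelihood_on=False``
    samples the prior only, which is how prior-recovery checks are run;
    ``site_effects=False`` pins every site effect at 0 (for models or
    oracle comparisons without the nesting layer).
    """
    hierarchical = data.flags.hierarchical
    ss = np.random.SeedSequence(mcmc.seed)
    children = ss.spawn(mcmc.n_chains)
    site_ptr, site_rows = _site_csr(data.site_index, data.n_sites)
    X = np.ascontiguousarray(data.X)
    Y = np.ascontiguousarray(data.y)

    # coefficient pairs that coincide on most design rows (indicator vs
    # intercept, interaction vs main effect): the kernel walks their
    # difference directly, which mixes these otherwise correlated blocks
    pairs = []
    cols = data.column_names
    for a, b in (("upland", "intercept"), ("burn_x_upland", "burn")):
        if a in cols and b in cols:
            pairs.append((cols.index(a), cols.index(b)))
    pair_cols = np.asarray(pairs if pairs else np.empty((0, 2)),
                           dtype=np.int64).reshape(-1, 2)

    S, p = data.n_species, data.n_coef
    all_draws, all_acc = [], []
    for c, child in enumerate(children):
        kernel_seed = int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        if initial_states and c in initial_states:
            state = {k: np.array(v, dtype=float) if np.ndim(v) else float(v)
                     for k, v in initial_states[c].items()}
        else:
            state = initialize(data, prior, child.spawn(1)[0],
                               fixed_r=fixed_r)
        if not site_effects:
            state["eps"] = np.zeros(data.n_sites)
        draws, acc = run_chain(
            X, Y, site_ptr, site_rows, pair_cols,
            1 if hierarchical else 0,
            0 if fixed_r is not None else 1,
            1 if likelihood_on else 0,
            1 if (site_effects and data.column_names
                  and data.column_names[0] == "intercept"
                  and np.all(X[:, 0] == 1.0)) else 0,
            1 if site_effects else 0,
            prior.mu_sd, prior.sigma_upper, prior.sigma_site_upper,
            prior.r_shape, prior.r_rate, prior.beta_sd,
            mcmc.n_iterations, mcmc.n_burnin, mcmc.thin, kernel_seed,
            np.atleast_2d(np.asarray(state["beta"], dtype=float)).copy(),
            np.asarray(state["eps"], dtype=float).copy(),
            np.asarray(state["mu"], dtype=float).copy(),
            np.asarray(state["sigma"], dtype=float).copy(),
            float(state["sigma_site"]), float(state["r"]),
        )
        all_draws.append(draws)
        all_acc.append(acc)

    draws = np.stack(all_draws)
    acc = np.stack(all_acc)
    if not hierarchical:  # drop the inert mu/sigma slots
        keep = np.r_[np.arange(S * p), np.arange(S * p + 2 * p, draws.shape[2])]
        draws = draws[:, :, keep]
        acc = acc[:, keep]

    names = parameter_names(data, hierarchical)
    if len(names) != draws.shape[2]:  # defensive: layout must match labels
        raise ContractError("parameter layout mismatch")

    rw = [i for i, n in enumerate(names)
          if not n.startswith("mu[")
          and not (fixed_r is not None and n == "r")
          and not (not site_effects and (n.startswith("eps[")
                                         or n == "sigma_site"))]
    mean_acc = float(acc[:, rw].mean()) if rw else 1.0
    if likelihood_on and not 0.1 <= mean_acc <= 0.6:
        warnings.warn(
            f"mean post-burn-in acceptance rate {mean_acc:.2f} outside "
            "[0.1, 0.6]; adaptation may not have settled",
            stacklevel=2,
        )
    return PosteriorChains(
        names=names, draws=draws, config=mcmc, acceptance=acc,
        meta={"hierarchical": hierarchical, "fixed_r": fixed_r,
              "species_ids": list(data.species_ids),
              "column_names": list(data.column_names),
              "site_ids": list(data.site_ids)},
    )
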