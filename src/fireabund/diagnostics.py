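"""Convergence checks, posterior summaries and goodness-of-fit.

Reporting conventions: posterior mean, SD and the 2.5th/97.5th
percentiles as the 95% credible interval; a coefficient is "significant"
when that interval excludes zero; chains are declared converged when the
Gelman-Rubin statistic is at most 1.1; a posterior-predictive Bayesian
p-value between .1 and .9 indicates adequate fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DegenerateInputError
from .model_core import ModelData
from .sampler import PosteriorChains

__all__ = [
    "gelman_rubin", "rhat_all", "summarize_posterior", "fit_report",
    "bayesian_p_value", "parameter_recovery", "PosteriorSummary",
]

RHAT_CONVERGED = 1.1
FIT_BAND = (0.1, 0.9)


def _rhat_from_matrix(x: np.ndarray) -> float:
    """Classic (non-split) potential scale reduction factor.

    x is (m chains, n iterations). With within-chain variance W and
    between-chain variance B, Rhat = sqrt(((n-1)/n W + B/n) / W).
    """
    m, n = x.shape
    if m < 2 or n < 2:
        raise DegenerateInputError("need >= 2 chains of >= 2 draws")
    W = float(np.mean(np.var(x, axis=1, ddof=1)))
    if W == 0.0:
        raise DegenerateInputError("zero within-chain variance")
    B = n * float(np.var(np.mean(x, axis=1), ddof=1))
    v_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(v_hat / W))


def gelman_rubin(chains: PosteriorChains, parameter: str,
                 split: bool = False) -> float:
    """Gelman-Rubin Rhat for one monitored parameter.

    ``split=True`` halves every chain first (the modern variant, more
    sensitive to within-chain trends); default is the classic statistic.
    """
    x = chains.get(parameter)
    if split:
        half = x.shape[1] // 2
        x = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    return _rhat_from_matrix(x)


def rhat_all(chains: PosteriorChains, split: bool = False,
             skip_fixed: bool = True) -> dict[str, float]:
    """Rhat for every monitored parameter; parameters held fixed during
    sampling (zero variance everywhere) are skipped when ``skip_fixed``."""
    out: dict[str, float] = {}
    for name in chains.names:
        x = chains.get(name)
        if skip_fixed and np.ptp(x) == 0.0:
            continue
        out[name] = gelman_rubin(chains, name, split=split)
    return out


@dataclass(frozen=True)
class PosteriorSummary:
    mean: float
    sd: float
    q2_5: float
    q97_5: float
    significant: bool


def summarize_posterior(chains: PosteriorChains,
                        parameter: str) -> PosteriorSummary:
    """Empirical mean/SD and central 95% interval of the pooled draws.

    Quantiles use type-7 linear interpolation (numpy's default), so
    summaries are bit-for-bit reproducible.
    """
    draws = chains.pooled(parameter)
    if draws.size == 0:
        raise DegenerateInputError("no retained draws")
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return PosteriorSummary(
        mean=float(draws.mean()),
        sd=float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
        q2_5=float(lo),
        q97_5=float(hi),
        significant=bool(lo > 0.0 or hi < 0.0),
    )


def fit_report(chains: PosteriorChains,
               include_rhat: bool = True) -> pd.DataFrame:
    """One-row-per-parameter summary table (mean, sd, q2.5, q97.5, rhat,
    significant) in the shape used for coefficient reporting."""
    rows = []
    rhats = rhat_all(chains) if include_rhat and chains.n_chains >= 2 else {}
    for name in chains.names:
        s = summarize_posterior(chains, name)
        rows.append({
            "parameter": name, "mean": s.mean, "sd": s.sd,
            "q2.5": s.q2_5, "q97.5": s.q97_5,
            "rhat": rhats.get(name, np.nan),
            "significant": s.significant,
        })
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# posterior-predictive goodness-of-fit


def _freeman_tukey(y: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Per-species Freeman-Tukey discrepancy sum_t (sqrt(y)-sqrt(lam))^2."""
    return np.sum((np.sqrt(y) - np.sqrt(lam)) ** 2, axis=-1)


def _chi_square(y: np.ndarray, lam: np.ndarray, r: float) -> np.ndarray:
    var = lam + lam * lam / r
    return np.sum((y - lam) ** 2 / var, axis=-1)


def bayesian_p_value(chains: PosteriorChains, data: ModelData, seed,
                     n_draws: int = 500,
                     discrepancy: str = "freeman_tukey",
                     _replicator: Callable | None = None) -> dict:
    """Posterior-predictive p-values per species and for the community.

    For each retained posterior draw, a replicate dataset is simulated at
    that draw's parameters; the p-value is the fraction of draws whose
    replicate discrepancy meets or exceeds (>=, ties count) the observed
    discrepancy. The community statistic sums discrepancies over species.
    Returns ``{"community": p, "species": {id: p}, "discrepancy": name}``.
    """
    if discrepancy not in ("freeman_tukey", "chi_square"):
        raise ContractError(f"unknown discrepancy {discrepancy!r}")
    rng = np.random.default_rng(seed)
    S, p = len(chains.meta["species_ids"]), len(chains.meta["column_names"])
    if list(data.species_ids) != list(chains.meta["species_ids"]):
        raise ContractError("chains and data species do not match")

    beta_idx = np.array([
        [chains.index(f"beta[{sp}][{col}]")
         for col in chains.meta["column_names"]]
        for sp in chains.meta["species_ids"]
    ])
    eps_idx = np.array([chains.index(n) for n in chains.names
                        if n.startswith("eps[")])
    r_idx = chains.index("r")

    flat = chains.draws.reshape(-1, chains.draws.shape[2])
    take = np.unique(np.linspace(0, flat.shape[0] - 1,
                                 min(n_draws, flat.shape[0])).astype(int))
    ge = np.zeros(S)
    ge_comm = 0
    for row in flat[take]:
        beta = row[beta_idx]
        eps = row[eps_idx]
        r = float(row[r_idx])
        lam = np.exp(beta @ data.X.T + eps[data.site_index][None, :])
        if _replicator is None:
            rep = rng.negative_binomial(r, r / (r + lam))
        else:
            rep = _replicator(lam, r, rng)
        if discrepancy == "freeman_tukey":
            t_obs = _freeman_tukey(data.y, lam)
            t_rep = _freeman_tukey(rep, lam)
        else:
            t_obs = _chi_square(data.y, lam, r)
            t_rep = _chi_square(rep, lam, r)
        ge += t_rep >= t_obs
        ge_comm += t_rep.sum() >= t_obs.sum()
    n = take.size
    return {
        "community": float(ge_comm / n),
        "species": {sp: float(ge[i] / n)
                    for i, sp in enumerate(chains.meta["species_ids"])},
        "discrepancy": discrepancy,
        "n_draws": int(n),
    }


def parameter_recovery(truth: Mapping[str, float],
                       reports: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Bias / RMSE / interval coverage of estimates across replicate fits.

    ``truth`` maps parameter names to generating values; ``reports`` are
    per-replicate :func:`fit_report` tables covering those names.
    """
    rows = []
    for name, tv in truth.items():
        ests, covered = [], []
        for rep in reports:
            if name not in rep.index:
                raise ContractError(
                    f"replicate report lacks parameter {name!r}"
                )
            ests.append(float(rep.loc[name, "mean"]))
            covered.append(
                float(rep.loc[name, "q2.5"]) <= tv <= float(rep.loc[name, "q97.5"])
            )
        ests_arr = np.asarray(ests)
        rows.append({
            "parameter": name,
            "truth": float(tv),
            "bias": float(ests_arr.mean() - tv),
            "rmse": float(np.sqrt(np.mean((ests_arr - tv) ** 2))),
            "coverage": float(np.mean(covered)),
            "n_replicates": len(ests),
        })
    return pd.DataFrame(rows).set_index("parameter")
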