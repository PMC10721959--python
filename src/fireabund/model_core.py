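"""The probabilistic model: negative-binomial counts with species-level
log-linear means, community hyperdistributions and a site random effect.

Counts N_ijk of species i at plot j on visit k follow

    N_ijk ~ NegBin(lambda_ijk, r),     Var = lambda + lambda^2 / r

with a dispersion r shared by all species of a community model, and

    log lambda_ijk = x_jk . beta_i + eps_site(j)

where each coefficient beta_ci is drawn from a community Normal
hyperdistribution Normal(mu_c, sigma_c) and site effects are
Normal(0, sigma_site). Vaguely informative hyperpriors close the model
(see :class:`PriorConfig`). Functions here are straightforward (loop- or
vector-level) reference implementations; the sampler uses compiled
kernels that are tested against these.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .errors import ContractError, DomainError, NumericalError
from .preprocessing import ModelFlags

__all__ = [
    "ModelData", "SpeciesCoefficients", "CommunityHyperparameters",
    "SiteEffects", "PriorConfig", "nb_log_pmf", "linear_predictor",
    "log_likelihood", "log_prior", "log_posterior", "simulate_counts",
]


@dataclass
class ModelData:
    """Design matrix + aligned counts, ready for likelihood evaluation.

    ``X`` is (n_obs, p) with one row per observed plot-visit; ``y`` is
    (n_species, n_obs); ``site_index`` maps each row to its site.
    """

    X: np.ndarray
    y: np.ndarray
    site_index: np.ndarray
    plot_index: np.ndarray
    n_sites: int
    species_ids: list[str]
    column_names: list[str]
    flags: ModelFlags
    site_ids: list[str] = field(default_factory=list)
    year_reference: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.site_index = np.asarray(self.site_index, dtype=np.int64)
        if self.y.ndim != 2 or self.y.shape[1] != self.X.shape[0]:
            raise ContractError("y must be (n_species, n_obs) aligned with X")
        if np.any(self.y < 0):
            raise ContractError("counts must be non-negative")
        if self.X.shape[0] and (self.site_index.min() < 0
                                or self.site_index.max() >= self.n_sites):
            raise ContractError("site_index out of bounds")

    @property
    def n_species(self) -> int:
        return self.y.shape[0]

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]


@dataclass
class SpeciesCoefficients:
    """Per-species regression coefficients, (n_species, p)."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if not np.isfinite(self.beta).all():
            raise ContractError("coefficients must be finite")


@dataclass
class SiteEffects:
    """Site-level Normal(0, sigma_site) random intercepts."""

    eps: np.ndarray

    def __post_init__(self) -> None:
        self.eps = np.asarray(self.eps, dtype=float)
        if not np.isfinite(self.eps).all():
            raise ContractError("site effects must be finite")


@dataclass
class CommunityHyperparameters:
    """Community means/SDs per coefficient, shared dispersion, site SD."""

    mu_beta: np.ndarray
    sigma_beta: np.ndarray
    r: float
    sigma_site: float

    def __post_init__(self) -> None:
        self.mu_beta = np.asarray(self.mu_beta, dtype=float)
        self.sigma_beta = np.asarray(self.sigma_beta, dtype=float)

    @property
    def valid(self) -> bool:
        return bool(
            np.all(self.sigma_beta > 0) and self.r > 0 and self.sigma_site > 0
            and np.isfinite(self.mu_beta).all()
            and np.isfinite(self.sigma_beta).all()
        )


@dataclass(frozen=True)
class PriorConfig:
    """Vaguely informative priors closing the hierarchy.

    mu_c ~ Normal(0, mu_sd); sigma_c, sigma_site ~ Uniform(0, sigma_upper);
    r ~ Gamma(r_shape, rate=r_rate). Non-hierarchical (single-species)
    models put Normal(0, beta_sd) directly on each coefficient.
    """

    mu_sd: float = 10.0
    sigma_upper: float = 10.0
    sigma_site_upper: float = 10.0
    r_shape: float = 0.1
    r_rate: float = 0.1
    beta_sd: float = 10.0
    include_hyperpriors: bool = True


_LOG_2PI = float(np.log(2.0 * np.pi))


def nb_log_pmf(y, lam, r):
    """Log pmf of the (mean, dispersion) negative binomial.

    P(y) = Gamma(y+r) / (Gamma(r) y!) * (r/(r+lam))^r * (lam/(r+lam))^y,
    so E[y] = lam and Var[y] = lam + lam^2/r; Poisson(lam) as r -> inf.
    Broadcasts over array arguments.
    """
    y = np.asarray(y)
    lam = np.asarray(lam, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(y < 0) or not np.issubdtype(np.asarray(y).dtype, np.integer):
        yf = np.asarray(y, dtype=float)
        if np.any(yf < 0) or np.any(yf != np.floor(yf)):
            raise DomainError("y must be a non-negative integer")
        y = yf.astype(np.int64)
    if np.any(lam <= 0) or np.any(r <= 0):
        raise DomainError("lam and r must be strictly positive")
    # -r*log1p(lam/r) == r*log(r/(r+lam)) but stays accurate as r -> inf
    if r.ndim == 0 and float(r) > 1e6:
        # large-r path: gammaln(y+r)-gammaln(r) loses precision, but
        # Gamma(y+r)/Gamma(r) = r^y * prod_k (1+k/r), and the y*log(r)
        # factor cancels against the tail of y*log(lam/(r+lam))
        ymax = int(np.max(y, initial=0))
        cum = np.concatenate([[0.0],
                              np.cumsum(np.log1p(np.arange(ymax) / float(r)))])
        out = (
            cum[y] - gammaln(y + 1)
            - (r + y) * np.log1p(lam / r)
            + y * np.log(lam)
        )
    else:
        out = (
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            - r * np.log1p(lam / r)
            + y * np.log(lam / (r + lam))
        )
    return out if out.ndim else float(out)


def linear_predictor(coefs: SpeciesCoefficients | np.ndarray,
                     row: Sequence[float], site_effect: float) -> float:
    """log lambda for one species at one observation row."""
    beta = coefs.beta if isinstance(coefs, SpeciesCoefficients) else np.asarray(coefs, float)
    beta = np.ravel(beta)
    row = np.asarray(row, dtype=float)
    if beta.shape != row.shape:
        raise ContractError(
            f"coefficient length {beta.shape} != design row length {row.shape}"
        )
    return float(beta @ row + site_effect)


def _lambda_matrix(beta: np.ndarray, eps: np.ndarray,
                   data: ModelData) -> np.ndarray:
    """(n_species, n_obs) matrix of means exp(X beta_i + eps_site)."""
    eta = beta @ data.X.T + eps[data.site_index][None, :]
    lam = np.exp(eta)
    if not np.isfinite(lam).all():
        bad = np.argwhere(~np.isfinite(lam))[0]
        raise NumericalError(
            f"non-finite mean at species {bad[0]}, row {bad[1]}"
        )
    return lam


def log_likelihood(coefs: SpeciesCoefficients, sites: SiteEffects,
                   r: float, data: ModelData) -> float:
    """Sum of NB log pmfs over every observed (species, plot, visit) cell."""
    if data.n_obs == 0:
        return 0.0
    lam = _lambda_matrix(coefs.beta, sites.eps, data)
    return float(np.sum(nb_log_pmf(data.y, lam, r)))


def log_prior(coefs: SpeciesCoefficients, sites: SiteEffects,
              hyper: CommunityHyperparameters,
              prior: PriorConfig = PriorConfig(),
              hierarchical: bool = True) -> float:
    """Log density of coefficients, site effects and hyperparameters.

    Out-of-support hyperparameter states return -inf (a rejected state)
    rather than raising, so samplers can propose freely.
    """
    if not hyper.valid:
        return -np.inf
    if hyper.sigma_beta.max(initial=0.0) >= prior.sigma_upper:
        return -np.inf
    if hyper.sigma_site >= prior.sigma_site_upper:
        return -np.inf

    def _normal_lp(x, mu, sd):
        z = (np.asarray(x) - mu) / sd
        return float(np.sum(-0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI))

    lp = 0.0
    if hierarchical:
        lp += _normal_lp(coefs.beta, hyper.mu_beta[None, :],
                         hyper.sigma_beta[None, :])
        if prior.include_hyperpriors:
            lp += _normal_lp(hyper.mu_beta, 0.0, prior.mu_sd)
            # sigma ~ U(0, upper): constant density inside the support
            lp += -np.log(prior.sigma_upper) * hyper.sigma_beta.size
    else:
        lp += _normal_lp(coefs.beta, 0.0, prior.beta_sd)
    lp += _normal_lp(sites.eps, 0.0, hyper.sigma_site)
    if prior.include_hyperpriors:
        lp += -np.log(prior.sigma_site_upper)
        # r ~ Gamma(shape, rate)
        a, b = prior.r_shape, prior.r_rate
        lp += float(a * np.log(b) - gammaln(a)
                    + (a - 1.0) * np.log(hyper.r) - b * hyper.r)
    return lp


def log_posterior(coefs: SpeciesCoefficients, sites: SiteEffects,
                  hyper: CommunityHyperparameters, data: ModelData,
                  prior: PriorConfig = PriorConfig(),
                  hierarchical: bool = True) -> float:
    lp = log_prior(coefs, sites, hyper, prior, hierarchical)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(coefs, sites, hyper.r, data)


def simulate_counts(coefs: SpeciesCoefficients, sites: SiteEffects,
                    r: float, data: ModelData,
                    rng: np.random.Generator | int) -> np.ndarray:
    """Forward-simulate a (n_species, n_obs) count matrix from the model.

    Used both by the synthetic-data generator and for posterior-predictive
    replication. Deterministic given the generator/seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    lam = _lambda_matrix(coefs.beta, sites.eps, data)
    # numpy's negative_binomial(n, p) has mean n(1-p)/p: n=r, p=r/(r+lam)
    return rng.negative_binomial(r, r / (r + lam)).astype(np.int64)
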