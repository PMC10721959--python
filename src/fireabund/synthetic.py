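"""Synthetic post-fire pollinator surveys with the structure the model
assumes, so the whole pipeline can be exercised and validated without
archived field data.

The generator emulates the study geometry: upland and meadow sites, each
a roughly homogeneous patch of one burn-severity class holding 3-5 plots
at least 100 m apart; plots visited 2-3 times per season over up to two
years; burn severity (RdNBR) continuous in upland but bimodal in meadow
(intermediate severities under-represented); floral richness and
abundance correlated with habitat and burn severity; species-level
coefficients drawn from community Normal hyperdistributions; counts
overdispersed negative-binomial. All randomness flows from one seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit

from . import preprocessing as prep
from .errors import InputError
from .model_core import (ModelData, SiteEffects, SpeciesCoefficients,
                         simulate_counts)
from .preprocessing import (CountDataset, CovariateSet, MEADOW, UPLAND,
                            ModelFlags, SNOWMELT_DATES)

__all__ = ["DesignConfig", "SyntheticStudy", "generate_design",
           "draw_parameters", "generate_dataset"]

# RdNBR severity components (mean, SD): unburned / moderate / high
_SEVERITY_COMPONENTS = ((30.0, 60.0), (450.0, 120.0), (950.0, 120.0))


@dataclass
class DesignConfig:
    """Everything the generator needs: geometry, covariate structure and
    the generating ("truth") parameter values.

    Defaults emulate the full study design (36 upland + 6 meadow sites,
    3-5 plots per site, 3 then 2 visits over two seasons); the
    :meth:`reduced` constructor builds the smaller balanced designs used
    for replicate studies.
    """

    n_upland_sites: int = 36
    n_meadow_sites: int = 6
    plots_per_site: tuple[int, int] = (3, 5)      # inclusive range
    visits_per_year: tuple[int, ...] = (3, 2)     # one entry per year
    years: tuple[int, ...] = (2016, 2017)
    #: fraction of upland sites surveyed in a single (random) year,
    #: emulating the unbalanced real design; meadows are always surveyed
    #: in every year
    upland_single_year_frac: float = 0.75
    #: meadow mixture weights over (unburned, moderate, high) severity
    #: components; the small middle weight leaves intermediate RdNBR
    #: under-represented in meadows
    meadow_severity_weights: tuple[float, float, float] = (0.45, 0.10, 0.45)
    rdnbr_within_site_sd: float = 40.0
    elevation_range: tuple[float, float] = (1300.0, 1800.0)
    snowmelt_day_range: tuple[int, int] = (5, 90)

    # floral covariates: latent-Gaussian scores correlated with burn
    n_frequent_plants: int = 30
    floral_burn_rho: float = -0.3   # latent corr(floral, burn) within habitat
    richness_logit_base: Mapping[str, float] = field(
        default_factory=lambda: {MEADOW: -0.4, UPLAND: -1.6})
    richness_logit_sd: float = 0.7
    inflor_log_base: Mapping[str, float] = field(
        default_factory=lambda: {MEADOW: 4.0, UPLAND: 2.5})
    inflor_log_sd: float = 0.6

    # community truth (standardized-covariate scale)
    n_species: int = 20
    mu_beta: Mapping[str, float] = field(default_factory=lambda: {
        prep.COL_INTERCEPT: 1.0, prep.COL_SNOWMELT: -0.2,
        prep.COL_RICHNESS: 0.4, prep.COL_INFLOR: 0.05,
        prep.COL_ELEVATION: -0.1, prep.COL_YEAR: -0.3,
        prep.COL_BURN: -0.3, prep.COL_BURN2_UPLAND: -0.3,
        prep.COL_BURN_X_UPLAND: 0.4, prep.COL_UPLAND: -0.8,
    })
    sigma_beta: Mapping[str, float] = field(default_factory=lambda: {
        prep.COL_INTERCEPT: 0.5, prep.COL_SNOWMELT: 0.3,
        prep.COL_RICHNESS: 0.3, prep.COL_INFLOR: 0.3,
        prep.COL_ELEVATION: 0.3, prep.COL_YEAR: 0.3,
        prep.COL_BURN: 0.3, prep.COL_BURN2_UPLAND: 0.3,
        prep.COL_BURN_X_UPLAND: 0.3, prep.COL_UPLAND: 0.3,
    })
    r: float = 2.0
    sigma_site: float = 0.3
    flags: ModelFlags = ModelFlags()

    def __post_init__(self) -> None:
        if self.n_upland_sites + self.n_meadow_sites < 1:
            raise InputError("need at least one site")
        if self.plots_per_site[0] < 1:
            raise InputError("plots_per_site must be positive")
        if len(self.visits_per_year) != len(self.years):
            raise InputError("visits_per_year must match years")
        if min(self.visits_per_year) < 1:
            raise InputError("need at least one visit per year")

    @classmethod
    def reduced(cls, n_species: int, n_sites: int, plots_per_site: int,
                n_visits: int, meadow_frac: float = 0.3,
                **overrides) -> "DesignConfig":
        """Balanced single-year design at a smaller scale, used for
        replicate simulate-and-fit studies (year column disabled since a
        single season carries no year contrast)."""
        n_meadow = max(2, round(n_sites * meadow_frac))
        kwargs = dict(
            n_upland_sites=n_sites - n_meadow,
            n_meadow_sites=n_meadow,
            plots_per_site=(plots_per_site, plots_per_site),
            visits_per_year=(n_visits,),
            years=(2016,),
            upland_single_year_frac=0.0,
            n_species=n_species,
            flags=ModelFlags(include_year=False),
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class SyntheticStudy:
    """A complete generated study plus the truth that generated it."""

    dataset: CountDataset
    covariates: CovariateSet           # raw (unstandardized)
    model_data: ModelData              # standardized design + counts
    truth: dict                        # sampler-parameter-name -> value
    config: DesignConfig
    seed: int


def _floral_latents(rng: np.random.Generator, burn_z: np.ndarray,
                    rho: float) -> np.ndarray:
    """Latent Gaussian floral score with corr ``rho`` to standardized burn."""
    noise = rng.normal(size=burn_z.shape)
    return rho * burn_z + np.sqrt(1.0 - rho * rho) * noise


def generate_design(config: DesignConfig, rng: np.random.Generator | int):
    """Draw the survey geometry and raw covariates.

    Returns ``(plots, visits, covariates)``: a plot table (plot_id,
    site_id, habitat, rdnbr, elevation_m), a visit table (plot_id,
    visit_id, date, year, observed) and a raw :class:`CovariateSet` on
    the (plot, visit-slot) grid.
    """
    import pandas as pd

    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    site_rows = []
    for h, n in ((UPLAND, config.n_upland_sites),
                 (MEADOW, config.n_meadow_sites)):
        for s in range(n):
            site_rows.append((f"{h[0]}{s + 1:02d}", h))

    plot_ids, plot_site, plot_hab = [], [], []
    rdnbr, elev = [], []
    lo, hi = config.plots_per_site
    w = np.asarray(config.meadow_severity_weights, dtype=float)
    w = w / w.sum()
    for site_id, hab in site_rows:
        if hab == MEADOW:
            comp = rng.choice(3, p=w)
        else:
            comp = rng.integers(0, 3)  # upland spans the severity range
        mean, sd = _SEVERITY_COMPONENTS[comp]
        site_rdnbr = rng.normal(mean, sd)
        site_elev = rng.uniform(*config.elevation_range)
        n_plots = int(rng.integers(lo, hi + 1))
        for p_i in range(n_plots):
            plot_ids.append(f"{site_id}_p{p_i + 1}")
            plot_site.append(site_id)
            plot_hab.append(hab)
            rdnbr.append(site_rdnbr + rng.normal(0, config.rdnbr_within_site_sd))
            elev.append(site_elev + rng.normal(0, 15.0))

    J = len(plot_ids)
    habitat = np.asarray(plot_hab, dtype=object)

    # visit-slot grid: one column per (year, within-year visit)
    slots = [(y, v) for y, nv in zip(config.years, config.visits_per_year)
             for v in range(nv)]
    K = len(slots)
    visit_ids = [f"y{y}_v{v + 1}" for y, v in slots]
    years_grid = np.tile([y for y, _ in slots], (J, 1))

    # which plot-visit cells are surveyed (meadows every year; some upland
    # sites only one year, emulating the real imbalance)
    observed = np.ones((J, K), dtype=bool)
    if len(config.years) > 1 and config.upland_single_year_frac > 0:
        site_year: dict[str, int | None] = {}
        for site_id, hab in site_rows:
            if hab == UPLAND and rng.random() < config.upland_single_year_frac:
                site_year[site_id] = int(rng.integers(0, len(config.years)))
            else:
                site_year[site_id] = None
        for j in range(J):
            only = site_year[plot_site[j]]
            if only is not None:
                for k, (y, _) in enumerate(slots):
                    observed[j, k] = (y == config.years[only])

    # snowmelt days: sorted within each year so visits are chronological
    snow = np.zeros((J, K), dtype=float)
    d_lo, d_hi = config.snowmelt_day_range
    for j in range(J):
        for y, nv in zip(config.years, config.visits_per_year):
            cols = [k for k, (yy, _) in enumerate(slots) if yy == y]
            days = np.sort(rng.integers(d_lo, d_hi + 1, size=nv))
            snow[j, cols] = days

    # floral covariates via latent scores correlated with burn severity
    burn_arr = np.asarray(rdnbr)
    burn_z = np.zeros(J)
    for hab in (MEADOW, UPLAND):
        m = habitat == hab
        if not m.any():
            continue
        sd = burn_arr[m].std()
        burn_z[m] = (burn_arr[m] - burn_arr[m].mean()) / (sd if sd > 0 else 1.0)
    richness = np.zeros((J, K), dtype=float)
    inflor = np.zeros((J, K), dtype=float)
    for k in range(K):
        z = _floral_latents(rng, burn_z, config.floral_burn_rho)
        for j in range(J):
            if not observed[j, k]:
                continue
            hab = habitat[j]
            logit_p = (config.richness_logit_base[hab]
                       + config.richness_logit_sd * z[j]
                       + rng.normal(0, 0.3))
            rich = rng.binomial(config.n_frequent_plants, expit(logit_p))
            la = (config.inflor_log_base[hab]
                  + config.inflor_log_sd * z[j] + rng.normal(0, 0.3))
            ab = float(np.round(np.exp(la)))
            if rich == 0:
                ab = 0.0
            else:
                ab = max(ab, float(rich))  # each blooming plant has >= 1
            richness[j, k] = rich
            inflor[j, k] = ab

    plots = pd.DataFrame({
        "plot_id": plot_ids, "site_id": plot_site, "habitat": plot_hab,
        "rdnbr": np.round(burn_arr, 1), "elevation_m": np.round(elev, 1),
    })
    visit_rows = []
    for j in range(J):
        for k, (y, v) in enumerate(slots):
            if not observed[j, k]:
                continue
            date = SNOWMELT_DATES.get(y, _dt.date(y, 6, 10)) \
                + _dt.timedelta(days=int(snow[j, k]))
            visit_rows.append({
                "plot_id": plot_ids[j], "visit_id": visit_ids[k],
                "date": date.isoformat(), "year": y,
            })
    visits = pd.DataFrame(visit_rows)

    cov = CovariateSet(
        burn=np.asarray(rdnbr, dtype=float), habitat=habitat,
        elevation=np.asarray(elev, dtype=float), snowmelt=snow,
        richness=richness, inflor=inflor, year=years_grid,
    )
    meta = {
        "plot_ids": plot_ids, "visit_ids": visit_ids,
        "plot_to_site": dict(zip(plot_ids, plot_site)),
        "observed": observed, "years": years_grid,
    }
    return plots, visits, cov, meta


def draw_parameters(config: DesignConfig, rng: np.random.Generator | int,
                    columns: list[str], n_sites: int):
    """Species coefficients i.i.d. Normal(mu_c, sigma_c) per column and
    site effects Normal(0, sigma_site), at the configured truth."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    mu = np.array([config.mu_beta[c] for c in columns])
    sig = np.array([config.sigma_beta[c] for c in columns])
    beta = rng.normal(mu[None, :], sig[None, :],
                      size=(config.n_species, len(columns)))
    eps = rng.normal(0.0, config.sigma_site, size=n_sites)
    return SpeciesCoefficients(beta), SiteEffects(eps)


def generate_dataset(config: DesignConfig, seed: int) -> SyntheticStudy:
    """Full generative pass: design -> standardized covariates -> truth
    coefficients -> negative-binomial counts. The returned truth dict is
    keyed by sampler parameter names, ready for recovery scoring."""
    rng = np.random.default_rng(seed)
    plots, visits, cov, meta = generate_design(config, rng)
    J, K = meta["observed"].shape

    species_ids = [f"sp{i + 1:02d}" for i in range(config.n_species)]
    dataset = CountDataset(
        species_ids=species_ids,
        counts=np.zeros((config.n_species, J, K), dtype=np.int64),
        observed=meta["observed"],
        plot_ids=meta["plot_ids"],
        visit_ids=meta["visit_ids"],
        plot_to_site=meta["plot_to_site"],
        years=meta["years"],
    )
    cov_std = prep.standardize_covariates(cov, dataset.observed)
    data = prep.build_design(dataset, cov_std, config.flags)

    coefs, sites = draw_parameters(config, rng, data.column_names,
                                   data.n_sites)
    y = simulate_counts(coefs, sites, config.r, data, rng)
    data.y = y
    # scatter row counts back onto the (plot, visit) grid
    obs_cells = np.argwhere(dataset.observed)
    assert obs_cells.shape[0] == data.n_obs
    for rix, (j, k) in enumerate(obs_cells):
        dataset.counts[:, j, k] = y[:, rix]

    truth: dict[str, float] = {}
    for c, col in enumerate(data.column_names):
        truth[f"mu[{col}]"] = float(config.mu_beta[col])
        truth[f"sigma[{col}]"] = float(config.sigma_beta[col])
        for i, sp in enumerate(species_ids):
            truth[f"beta[{sp}][{col}]"] = float(coefs.beta[i, c])
    for s, sid in enumerate(data.site_ids):
        truth[f"eps[{sid}]"] = float(sites.eps[s])
    truth["r"] = float(config.r)
    truth["sigma_site"] = float(config.sigma_site)

    return SyntheticStudy(dataset=dataset, covariates=cov,
                          model_data=data, truth=truth,
                          config=config, seed=int(seed))
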