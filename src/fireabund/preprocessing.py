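"""Raw survey tables -> standardized model design arrays.

The survey design is hierarchical: sites hold 3-5 plots, each plot is
visited 2-3 times per season, and on every visit two kinds of records are
made: pollinator counts per species, and floral records from eight 1-m^2
quadrats. This module applies the filtering and scaling rules the analysis
requires:

* plants kept as "frequently visited" when they received at least 10
  recorded flower visits overall;
* floral abundance = summed open inflorescences of frequent plants per
  plot-visit, floral richness = number of distinct frequent plants in
  bloom across the union of the plot's quadrats;
* species enter community models only when detected in >= 3 distinct plots;
* continuous covariates are centred/scaled to mean 0, SD 1 (sample SD);
  the two floral covariates are standardized within habitat, because
  their habitat-level baseline belongs to the categorical habitat term;
* the quadratic burn-severity column is forced to 0 for meadow plots.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np

from .errors import ContractError, DegenerateInputError, InputError

MEADOW = "meadow"
UPLAND = "upland"
HABITATS = (MEADOW, UPLAND)

#: regional snowmelt dates used to compute the days-since-snowmelt covariate
SNOWMELT_DATES: Mapping[int, _dt.date] = {
    2016: _dt.date(2016, 6, 6),
    2017: _dt.date(2017, 6, 18),
}

# design-matrix column names, in canonical order
COL_INTERCEPT = "intercept"
COL_SNOWMELT = "snowmelt"
COL_RICHNESS = "richness"
COL_INFLOR = "inflor"
COL_ELEVATION = "elevation"
COL_YEAR = "year"
COL_BURN = "burn"
COL_BURN2_UPLAND = "burn2_upland"
COL_BURN_X_UPLAND = "burn_x_upland"
COL_UPLAND = "upland"


@dataclass(frozen=True)
class QuadratRecord:
    """One plant species observed in bloom in one 1-m^2 quadrat."""

    plot_id: str
    visit_id: str
    quadrat_index: int
    plant_species: str
    open_inflorescences: int

    def __post_init__(self) -> None:
        if not 1 <= self.quadrat_index <= 8:
            raise InputError(
                f"quadrat_index must be in 1..8, got {self.quadrat_index}"
            )
        if self.open_inflorescences < 0:
            raise InputError("open_inflorescences must be non-negative")


@dataclass(frozen=True)
class VisitationRecord:
    """One captured flower visit: a pollinator on a plant at a plot-visit."""

    plant_species: str
    pollinator_species: str
    plot_id: str
    visit_id: str


@dataclass
class CountDataset:
    """Per-species pollinator counts on the (plot, visit-slot) grid.

    ``counts`` is (n_species, n_plots, n_visit_slots); ``observed`` marks
    which plot-visit cells were actually surveyed (the design is unbalanced
    across years). Counts in unobserved cells are ignored everywhere.
    """

    species_ids: list[str]
    counts: np.ndarray
    observed: np.ndarray
    plot_ids: list[str]
    visit_ids: list[str]
    plot_to_site: dict[str, str]
    years: np.ndarray  # (n_plots, n_visit_slots) calendar year per cell

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.observed = np.asarray(self.observed, dtype=bool)
        S, J, K = self.counts.shape
        if len(self.species_ids) != S or len(self.plot_ids) != J:
            raise InputError("CountDataset index lengths do not match counts")
        if self.observed.shape != (J, K):
            raise InputError("observed mask shape does not match counts")
        if np.any(self.counts[:, self.observed] < 0):
            raise InputError("counts must be non-negative where observed")
        missing = set(self.plot_ids) - set(self.plot_to_site)
        if missing:
            raise InputError(f"plots without a site mapping: {sorted(missing)}")

    @property
    def n_species(self) -> int:
        return self.counts.shape[0]

    @property
    def site_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.plot_ids:
            seen.setdefault(self.plot_to_site[p], None)
        return list(seen)


@dataclass
class CovariateSet:
    """Plot-level and visit-level predictors, raw or standardized.

    ``burn``/``elevation``/``habitat`` are per plot; ``snowmelt``,
    ``richness``, ``inflor`` and ``year`` are per (plot, visit-slot).
    After :func:`standardize_covariates` the ``standardized`` flag is set
    and ``scalers`` records every (mean, sd) used, keyed by covariate name
    (floral covariates carry one entry per habitat stratum).
    """

    burn: np.ndarray
    habitat: np.ndarray
    elevation: np.ndarray
    snowmelt: np.ndarray
    richness: np.ndarray
    inflor: np.ndarray
    year: np.ndarray
    standardized: bool = False
    scalers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.habitat = np.asarray(self.habitat, dtype=object)
        levels = set(self.habitat.tolist())
        if not levels <= set(HABITATS):
            raise InputError(f"unknown habitat levels: {levels - set(HABITATS)}")


# ---------------------------------------------------------------------------
# filtering rules


def filter_frequent_plants(
    records: Iterable[VisitationRecord], min_visits: int = 10
) -> set[str]:
    """Plant species receiving at least ``min_visits`` recorded flower
    visits in total. These are the plants whose bloom defines the floral
    covariates; rarely- and never-visited plants are dropped."""
    if min_visits < 1:
        raise InputError("min_visits must be >= 1")
    tally: dict[str, int] = {}
    for rec in records:
        tally[rec.plant_species] = tally.get(rec.plant_species, 0) + 1
    return {sp for sp, n in tally.items() if n >= min_visits}


def compute_floral_metrics(
    quadrats: Iterable[QuadratRecord],
    frequent: set[str],
    plot_visits: Sequence[tuple[str, str]],
    master_plants: set[str] | None = None,
) -> dict[tuple[str, str], tuple[int, int]]:
    """Per plot-visit floral (abundance, richness) from quadrat records.

    Abundance sums open inflorescences over records of frequent plants;
    richness counts distinct frequent plants in bloom anywhere in the
    plot's eight quadrats. Plot-visits with no qualifying record get (0, 0).
    """
    index = set(plot_visits)
    abund: dict[tuple[str, str], int] = {pv: 0 for pv in plot_visits}
    blooming: dict[tuple[str, str], set[str]] = {pv: set() for pv in plot_visits}
    for rec in quadrats:
        key = (rec.plot_id, rec.visit_id)
        if key not in index:
            raise InputError(f"quadrat record for unknown plot-visit {key}")
        if master_plants is not None and rec.plant_species not in master_plants:
            raise InputError(
                f"quadrat record names plant {rec.plant_species!r} absent "
                "from the master plant list"
            )
        if rec.plant_species in frequent:
            abund[key] += rec.open_inflorescences
            if rec.open_inflorescences > 0:
                blooming[key].add(rec.plant_species)
    return {pv: (abund[pv], len(blooming[pv])) for pv in plot_visits}


def days_since_snowmelt(visit_date: _dt.date, snowmelt_date: _dt.date) -> int:
    """Whole days between a survey visit and the regional snowmelt date."""
    delta = (visit_date - snowmelt_date).days
    if delta < 0:
        raise InputError(
            f"visit {visit_date} precedes snowmelt {snowmelt_date}"
        )
    return delta


def pool_double_surveys(period1: np.ndarray, period2: np.ndarray) -> np.ndarray:
    """Element-wise sum of the two consecutive sampling periods of a visit
    (used when no detection decline justifies a removal model)."""
    a = np.asarray(period1)
    b = np.asarray(period2)
    if a.shape != b.shape:
        raise InputError(
            f"period count tables differ in shape: {a.shape} vs {b.shape}"
        )
    return a + b


def filter_community_species(
    dataset: CountDataset, min_plots: int = 3
) -> CountDataset:
    """Retain species detected in at least ``min_plots`` distinct plots.

    Community models borrow strength across species but need each member
    to carry some information; species seen at fewer plots are dropped
    (species order is preserved)."""
    if min_plots < 1:
        raise InputError("min_plots must be >= 1")
    present = (dataset.counts > 0) & dataset.observed[None, :, :]
    plots_per_species = present.any(axis=2).sum(axis=1)
    keep = plots_per_species >= min_plots
    if keep.sum() < 2:
        warnings.warn(
            "fewer than 2 species remain; community models typically need "
            "6 or more species",
            stacklevel=2,
        )
    return CountDataset(
        species_ids=[s for s, k in zip(dataset.species_ids, keep) if k],
        counts=dataset.counts[keep],
        observed=dataset.observed,
        plot_ids=dataset.plot_ids,
        visit_ids=dataset.visit_ids,
        plot_to_site=dict(dataset.plot_to_site),
        years=dataset.years,
    )


# ---------------------------------------------------------------------------
# standardization


def standardize_global(values) -> tuple[np.ndarray, float, float]:
    """Centre and scale to mean 0, SD 1 (sample SD, n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise DegenerateInputError("cannot standardize a constant vector")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return (x - mean) / sd, mean, sd


def standardize_within_habitat(
    values, habitat
) -> tuple[np.ndarray, dict[str, tuple[float, float]]]:
    """Standardize within each habitat stratum separately, so the covariate
    measures deviation from its habitat mean and the baseline habitat
    difference is carried by the categorical habitat term."""
    x = np.asarray(values, dtype=float)
    hab = np.asarray(habitat, dtype=object)
    if x.shape != hab.shape:
        raise InputError("values and habitat must have the same shape")
    out = np.empty_like(x)
    stats: dict[str, tuple[float, float]] = {}
    for level in sorted(set(hab.ravel().tolist())):
        mask = hab == level
        if np.unique(x[mask]).size < 2:
            raise DegenerateInputError(
                f"habitat stratum {level!r} has constant values"
            )
        z, m, s = standardize_global(x[mask])
        out[mask] = z
        stats[level] = (m, s)
    return out, stats


def standardize_covariates(
    cov: CovariateSet, observed: np.ndarray
) -> CovariateSet:
    """Standardize every continuous covariate of a :class:`CovariateSet`.

    Snowmelt, elevation and burn severity are standardized globally over
    observed cells/plots; floral richness and abundance within habitat.
    Statistics are computed on observed plot-visit cells only and stored in
    ``scalers`` so the transform is invertible.
    """
    if cov.standardized:
        return cov
    observed = np.asarray(observed, dtype=bool)
    scalers: dict = {}

    burn_z, m, s = standardize_global(cov.burn)
    scalers["burn"] = (m, s)
    elev_z, m, s = standardize_global(cov.elevation)
    scalers["elevation"] = (m, s)

    snow_z = np.array(cov.snowmelt, dtype=float)
    z, m, s = standardize_global(cov.snowmelt[observed])
    snow_z[observed] = z
    scalers["snowmelt"] = (m, s)

    # floral covariates: per-habitat statistics over observed cells
    hab_cells = np.broadcast_to(
        cov.habitat[:, None], cov.richness.shape
    )[observed]
    rich_z = np.array(cov.richness, dtype=float)
    rich_z[observed], stats = standardize_within_habitat(
        cov.richness[observed].astype(float), hab_cells
    )
    scalers["richness"] = stats
    infl_z = np.array(cov.inflor, dtype=float)
    infl_z[observed], stats = standardize_within_habitat(
        cov.inflor[observed].astype(float), hab_cells
    )
    scalers["inflor"] = stats

    return replace(
        cov,
        burn=burn_z,
        elevation=elev_z,
        snowmelt=snow_z,
        richness=rich_z,
        inflor=infl_z,
        standardized=True,
        scalers=scalers,
    )


# ---------------------------------------------------------------------------
# design builder


@dataclass(frozen=True)
class ModelFlags:
    """Which optional design columns a model variant includes.

    The community and hummingbird models use everything; the butterfly
    variant drops year and the quadratic burn term (single-year,
    two-severity-class sampling), and single-species variants replace the
    community hyperdistribution with fixed vague priors.
    """

    include_year: bool = True
    include_quadratic: bool = True
    include_habitat_main: bool = True
    hierarchical: bool = True

    def columns(self) -> list[str]:
        cols = [COL_INTERCEPT, COL_SNOWMELT, COL_RICHNESS, COL_INFLOR,
                COL_ELEVATION]
        if self.include_year:
            cols.append(COL_YEAR)
        cols.append(COL_BURN)
        if self.include_quadratic:
            cols.append(COL_BURN2_UPLAND)
        cols.append(COL_BURN_X_UPLAND)
        if self.include_habitat_main:
            cols.append(COL_UPLAND)
        return cols


BUTTERFLY_FLAGS = ModelFlags(include_year=False, include_quadratic=False,
                             hierarchical=False)
HUMMINGBIRD_FLAGS = ModelFlags(hierarchical=False)


def build_design(dataset: CountDataset, cov: CovariateSet,
                 flags: ModelFlags = ModelFlags()):
    """Assemble the per-observation design matrix and aligned count matrix.

    One row per observed (plot, visit) cell; columns per ``flags``. Burn
    severity enters linearly everywhere, quadratically only in upland
    plots (the meadow quadratic column is structurally zero), and
    interacts with the upland indicator. Returns a
    :class:`~fireabund.model_core.ModelData`.
    """
    from .model_core import ModelData  # deferred: model_core is downstream

    if not cov.standardized:
        raise ContractError(
            "covariates must be standardized before building the design; "
            "call standardize_covariates first"
        )
    J, K = dataset.observed.shape
    if cov.snowmelt.shape != (J, K):
        raise InputError("covariate grid does not match the count grid")

    site_ids = dataset.site_ids
    site_index_of = {s: i for i, s in enumerate(site_ids)}
    upland = (cov.habitat == UPLAND).astype(float)
    year_ref = int(dataset.years[dataset.observed].min())

    cols = flags.columns()
    rows, y_cols, site_idx, plot_idx = [], [], [], []
    for j in range(J):
        for k in range(K):
            if not dataset.observed[j, k]:
                continue
            b = cov.burn[j]
            row = {
                COL_INTERCEPT: 1.0,
                COL_SNOWMELT: cov.snowmelt[j, k],
                COL_RICHNESS: cov.richness[j, k],
                COL_INFLOR: cov.inflor[j, k],
                COL_ELEVATION: cov.elevation[j],
                COL_YEAR: float(dataset.years[j, k] != year_ref),
                COL_BURN: b,
                COL_BURN2_UPLAND: b * b * upland[j],
                COL_BURN_X_UPLAND: b * upland[j],
                COL_UPLAND: upland[j],
            }
            rows.append([row[c] for c in cols])
            y_cols.append(dataset.counts[:, j, k])
            site_idx.append(site_index_of[dataset.plot_to_site[dataset.plot_ids[j]]])
            plot_idx.append(j)

    X = np.asarray(rows, dtype=float)
    if not np.isfinite(X).all():
        raise InputError("design matrix contains non-finite values")
    return ModelData(
        X=X,
        y=np.asarray(y_cols, dtype=np.int64).T.copy(),
        site_index=np.asarray(site_idx, dtype=np.int64),
        plot_index=np.asarray(plot_idx, dtype=np.int64),
        n_sites=len(site_ids),
        species_ids=list(dataset.species_ids),
        column_names=cols,
        flags=flags,
        site_ids=site_ids,
        year_reference=year_ref,
    )
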