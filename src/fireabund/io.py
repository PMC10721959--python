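"""Reading and writing the pipeline's delimited-text interchange formats.

Four CSV tables describe a study (counts.csv, plots.csv, visits.csv,
quadrats.csv, plus visitation.csv for the frequent-plant filter); the
prepared design is a single structured JSON file; chains are one CSV per
chain plus a JSON run manifest. Everything round-trips losslessly.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocessing as prep
from .errors import InputError
from .model_core import ModelData
from .preprocessing import (CountDataset, CovariateSet, ModelFlags,
                            SNOWMELT_DATES, QuadratRecord, VisitationRecord)
from .sampler import McmcConfig, PosteriorChains

__all__ = [
    "write_study_csvs", "load_study_csvs", "save_model_data",
    "load_model_data", "write_chains", "read_chains",
]


# ---------------------------------------------------------------------------
# synthetic study -> CSV tables


def write_study_csvs(study, outdir: str | Path) -> dict[str, Path]:
    """Emit a generated study as the raw survey tables the preprocessing
    stage reads, plus truth.json.

    Quadrat records are constructed to reproduce the study's floral
    metrics exactly (abundance distributed over that many blooming
    frequent plants); a visitation table is emitted so the >=10-visit
    plant filter is exercisable end to end. Occasional records of rarely
    visited plants are included and must be filtered out downstream.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([study.seed, 0xF10]))
    ds, cov, config = study.dataset, study.covariates, study.config

    plots, visits, _, _ = _tables_from_study(study)
    plots.to_csv(outdir / "plots.csv", index=False)
    visits.to_csv(outdir / "visits.csv", index=False)

    count_rows = []
    obs = np.argwhere(ds.observed)
    for i, sp in enumerate(ds.species_ids):
        for j, k in obs:
            count_rows.append({
                "species_id": sp, "plot_id": ds.plot_ids[j],
                "site_id": ds.plot_to_site[ds.plot_ids[j]],
                "visit_id": ds.visit_ids[k],
                "year": int(ds.years[j, k]),
                "count": int(ds.counts[i, j, k]),
            })
    pd.DataFrame(count_rows).to_csv(outdir / "counts.csv", index=False)

    frequent = [f"plantF{i + 1:02d}" for i in range(config.n_frequent_plants)]
    rare = [f"plantR{i + 1:02d}" for i in range(10)]

    quad_rows = []
    for j, k in obs:
        rich = int(cov.richness[j, k])
        abund = int(cov.inflor[j, k])
        if rich > 0:
            chosen = rng.choice(config.n_frequent_plants, size=rich,
                                replace=False)
            extra = rng.multinomial(abund - rich, np.full(rich, 1.0 / rich))
            for idx, sp_i in enumerate(chosen):
                quad_rows.append({
                    "plot_id": ds.plot_ids[j], "visit_id": ds.visit_ids[k],
                    "quadrat": int(rng.integers(1, 9)),
                    "plant_species": frequent[sp_i],
                    "open_inflorescences": int(1 + extra[idx]),
                })
        if rng.random() < 0.3:  # a rarely-visited plant in bloom
            quad_rows.append({
                "plot_id": ds.plot_ids[j], "visit_id": ds.visit_ids[k],
                "quadrat": int(rng.integers(1, 9)),
                "plant_species": rare[int(rng.integers(0, len(rare)))],
                "open_inflorescences": int(rng.integers(1, 6)),
            })
    pd.DataFrame(quad_rows).to_csv(outdir / "quadrats.csv", index=False)

    # visitation: frequent plants get >= 10 visits, rare ones fewer
    pv = [(ds.plot_ids[j], ds.visit_ids[k]) for j, k in obs]
    vis_rows = []
    for p in frequent:
        for _ in range(10 + int(rng.poisson(15))):
            j, k = pv[int(rng.integers(0, len(pv)))]
            vis_rows.append({"plant_species": p,
                             "pollinator_species":
                                 ds.species_ids[int(rng.integers(0, len(ds.species_ids)))],
                             "plot_id": j, "visit_id": k})
    for p in rare:
        for _ in range(int(rng.integers(0, 5))):
            j, k = pv[int(rng.integers(0, len(pv)))]
            vis_rows.append({"plant_species": p,
                             "pollinator_species":
                                 ds.species_ids[int(rng.integers(0, len(ds.species_ids)))],
                             "plot_id": j, "visit_id": k})
    pd.DataFrame(vis_rows).to_csv(outdir / "visitation.csv", index=False)

    with open(outdir / "truth.json", "w") as fh:
        json.dump({"seed": study.seed, "truth": study.truth}, fh, indent=1)
    return {n: outdir / f"{n}.csv"
            for n in ("counts", "plots", "visits", "quadrats", "visitation")}


def _tables_from_study(study):
    ds, cov = study.dataset, study.covariates
    plots = pd.DataFrame({
        "plot_id": ds.plot_ids,
        "site_id": [ds.plot_to_site[p] for p in ds.plot_ids],
        "habitat": cov.habitat,
        "rdnbr": cov.burn,
        "elevation_m": cov.elevation,
    })
    rows = []
    for j, k in np.argwhere(ds.observed):
        year = int(ds.years[j, k])
        melt = SNOWMELT_DATES.get(year, _dt.date(year, 6, 10))
        date = melt + _dt.timedelta(days=int(cov.snowmelt[j, k]))
        rows.append({"plot_id": ds.plot_ids[j],
                     "visit_id": ds.visit_ids[k],
                     "date": date.isoformat(), "year": year})
    return plots, pd.DataFrame(rows), None, None


# ---------------------------------------------------------------------------
# CSV tables -> CountDataset + raw CovariateSet


def load_study_csvs(indir: str | Path, min_plant_visits: int = 10
                    ) -> tuple[CountDataset, CovariateSet]:
    """Read the raw survey tables and rebuild the count/covariate grids,
    applying the frequent-plant filter to derive the floral covariates."""
    indir = Path(indir)
    for name in ("counts", "plots", "visits", "quadrats"):
        if not (indir / f"{name}.csv").exists():
            raise InputError(f"missing input table {name}.csv in {indir}")
    plots = pd.read_csv(indir / "plots.csv")
    visits = pd.read_csv(indir / "visits.csv")
    counts = pd.read_csv(indir / "counts.csv")
    quadrats = pd.read_csv(indir / "quadrats.csv")

    plot_ids = plots["plot_id"].tolist()
    plot_pos = {p: j for j, p in enumerate(plot_ids)}
    visit_ids = sorted(visits["visit_id"].unique().tolist())
    visit_pos = {v: k for k, v in enumerate(visit_ids)}
    J, K = len(plot_ids), len(visit_ids)

    observed = np.zeros((J, K), dtype=bool)
    years = np.zeros((J, K), dtype=np.int64)
    snow = np.zeros((J, K), dtype=float)
    melt_fallback = {int(y): _dt.date.fromisoformat(g["date"].min())
                     for y, g in visits.groupby("year")}
    for _, row in visits.iterrows():
        j, k = plot_pos[row["plot_id"]], visit_pos[row["visit_id"]]
        observed[j, k] = True
        year = int(row["year"])
        years[j, k] = year
        melt = SNOWMELT_DATES.get(year, melt_fallback[year])
        snow[j, k] = prep.days_since_snowmelt(
            _dt.date.fromisoformat(row["date"]), melt)
    years[~observed] = years[observed].min() if observed.any() else 0

    species_ids = sorted(counts["species_id"].unique().tolist())
    sp_pos = {s: i for i, s in enumerate(species_ids)}
    cmat = np.zeros((len(species_ids), J, K), dtype=np.int64)
    for _, row in counts.iterrows():
        if row["plot_id"] not in plot_pos:
            raise InputError(f"counts.csv names unknown plot {row['plot_id']!r}")
        cmat[sp_pos[row["species_id"]], plot_pos[row["plot_id"]],
             visit_pos[row["visit_id"]]] = int(row["count"])

    dataset = CountDataset(
        species_ids=species_ids, counts=cmat, observed=observed,
        plot_ids=plot_ids, visit_ids=visit_ids,
        plot_to_site=dict(zip(plots["plot_id"], plots["site_id"])),
        years=years,
    )

    if (indir / "visitation.csv").exists():
        vis = pd.read_csv(indir / "visitation.csv")
        records = [VisitationRecord(r["plant_species"],
                                    r["pollinator_species"],
                                    r["plot_id"], r["visit_id"])
                   for _, r in vis.iterrows()]
        frequent = prep.filter_frequent_plants(records, min_plant_visits)
        master = set(vis["plant_species"]) | set(quadrats["plant_species"])
    else:
        frequent = set(quadrats["plant_species"])
        master = set(frequent)

    qrecords = [QuadratRecord(r["plot_id"], r["visit_id"], int(r["quadrat"]),
                              r["plant_species"], int(r["open_inflorescences"]))
                for _, r in quadrats.iterrows()]
    pv = [(plot_ids[j], visit_ids[k]) for j, k in np.argwhere(observed)]
    metrics = prep.compute_floral_metrics(qrecords, frequent, pv, master)
    richness = np.zeros((J, K), dtype=float)
    inflor = np.zeros((J, K), dtype=float)
    for (p, v), (ab, ri) in metrics.items():
        richness[plot_pos[p], visit_pos[v]] = ri
        inflor[plot_pos[p], visit_pos[v]] = ab

    cov = CovariateSet(
        burn=plots["rdnbr"].to_numpy(dtype=float),
        habitat=plots["habitat"].to_numpy(dtype=object),
        elevation=plots["elevation_m"].to_numpy(dtype=float),
        snowmelt=snow, richness=richness, inflor=inflor, year=years,
    )
    return dataset, cov


# ---------------------------------------------------------------------------
# prepared design


def save_model_data(data: ModelData, path: str | Path,
                    scalers: dict | None = None) -> None:
    payload = {
        "X": data.X.tolist(),
        "y": data.y.tolist(),
        "site_index": data.site_index.tolist(),
        "plot_index": data.plot_index.tolist(),
        "n_sites": data.n_sites,
        "species_ids": data.species_ids,
        "column_names": data.column_names,
        "site_ids": data.site_ids,
        "year_reference": data.year_reference,
        "flags": vars(data.flags) if not isinstance(data.flags, dict)
                 else data.flags,
        "scalers": scalers or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model_data(path: str | Path) -> ModelData:
    with open(path) as fh:
        d = json.load(fh)
    return ModelData(
        X=np.asarray(d["X"], dtype=float),
        y=np.asarray(d["y"], dtype=np.int64),
        site_index=np.asarray(d["site_index"], dtype=np.int64),
        plot_index=np.asarray(d["plot_index"], dtype=np.int64),
        n_sites=int(d["n_sites"]),
        species_ids=list(d["species_ids"]),
        column_names=list(d["column_names"]),
        flags=ModelFlags(**d["flags"]),
        site_ids=list(d["site_ids"]),
        year_reference=int(d["year_reference"]),
    )


# ---------------------------------------------------------------------------
# chains


def write_chains(chains: PosteriorChains, outdir: str | Path) -> None:
    """One CSV per chain (iteration + parameter columns) plus a JSON
    manifest with the run configuration and acceptance rates."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for c in range(chains.n_chains):
        df = pd.DataFrame(chains.draws[c], columns=chains.names)
        df.insert(0, "iteration", np.arange(chains.n_kept))
        df.to_csv(outdir / f"chain{c + 1}.csv", index=False,
                  float_format="%.17g")
    manifest = {
        "n_chains": chains.n_chains,
        "config": vars(chains.config),
        "names": chains.names,
        "acceptance": chains.acceptance.tolist(),
        "meta": chains.meta,
    }
    with open(outdir / "chains_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_chains(indir: str | Path) -> PosteriorChains:
    indir = Path(indir)
    with open(indir / "chains_manifest.json") as fh:
        manifest = json.load(fh)
    draws = []
    for c in range(manifest["n_chains"]):
        df = pd.read_csv(indir / f"chain{c + 1}.csv",
                         float_precision="round_trip")
        draws.append(df[manifest["names"]].to_numpy())
    return PosteriorChains(
        names=list(manifest["names"]),
        draws=np.stack(draws),
        config=McmcConfig(**manifest["config"]),
        acceptance=np.asarray(manifest["acceptance"]),
        meta=manifest.get("meta", {}),
    )
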