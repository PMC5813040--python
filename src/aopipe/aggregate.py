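"""Aggregation of station-level records into multi-scale summaries.

Per station and species, abundance is the individual count divided by the
sampled surface (individuals m-2) and biomass the summed flesh AFDM divided
by the same surface (g m-2); presence is count-based.  Stations where a
species was not found carry explicit zeros: absence is defined over the
dense grid of visited stations x the species universe.

Three analysis scales are derived from the station table:

* ``regional_temporal`` — one unit per year over the whole study area;
* ``local_temporal``    — one unit per tidal basin x year;
* ``spatial``           — the same basin x year units, regrouped per year.

For every unit, occupancy is the number of occupied stations over the number
of visited stations, and the *local mean* abundance/biomass is the mean over
occupied stations only (so local mean >= all-station mean, with equality only
at full occupancy).  Basin-years that were never sampled contribute to
neither numerator nor denominator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALES = ("regional_temporal", "local_temporal", "spatial")


def station_summaries(stations: pd.DataFrame,
                      individuals: pd.DataFrame) -> pd.DataFrame:
    """Dense station x species table of abundance, biomass and presence.

    ``individuals`` may be a raw or a QC'ed table; when a ``qc_flag`` column
    is present, removed records are excluded, and ``afdm_g_clean`` is used
    for biomass when available.  Raises on duplicate (station, year) rows in
    ``stations`` and on individuals referencing unknown station-years.
    """
    dup = stations.duplicated(["station_id", "year"])
    if dup.any():
        bad = stations.loc[dup, ["station_id", "year"]].head(5).to_dict("records")
        raise ValueError(f"duplicate (station_id, year) rows in stations: {bad}")
    if (stations["area_m2"] <= 0).any():
        raise ValueError("non-positive sampled area in stations")

    ind = individuals
    if "qc_flag" in ind.columns:
        ind = ind[ind["qc_flag"] != "removed"]
    mass_col = "afdm_g_clean" if "afdm_g_clean" in ind.columns else "afdm_g"

    key = pd.MultiIndex.from_frame(stations[["station_id", "year"]])
    ind_key = pd.MultiIndex.from_frame(ind[["station_id", "year"]])
    orphan = ~ind_key.isin(key)
    if orphan.any():
        bad = ind.loc[orphan, ["station_id", "year"]].drop_duplicates().head(5)
        raise ValueError("individual records reference unvisited station-years: "
                         f"{bad.to_dict('records')}")

    species = np.sort(ind["species"].unique())
    agg = (ind.groupby(["station_id", "year", "species"], sort=False)
           .agg(count=("species", "size"), mass=(mass_col, "sum"))
           .reset_index())

    base = stations[["station_id", "year", "basin_id", "area_m2"]]
    grid = base.merge(pd.DataFrame({"species": species}), how="cross")
    dense = grid.merge(agg, on=["station_id", "year", "species"], how="left")
    dense["count"] = dense["count"].fillna(0).astype(int)
    dense["mass"] = dense["mass"].fillna(0.0)
    dense["abundance"] = dense["count"] / dense["area_m2"]
    dense["biomass"] = dense["mass"] / dense["area_m2"]
    dense["present"] = (dense["count"] > 0).astype(int)
    return dense[["station_id", "year", "basin_id", "species",
                  "count", "abundance", "biomass", "present"]]


def scale_summaries(station_table: pd.DataFrame, scale: str) -> pd.DataFrame:
    """Per-unit occupancy and occupied-only means at one analysis scale.

    Units are years (regional) or basin x year (local and spatial — the
    spatial view reuses the same basin-year summaries, regrouped downstream).
    Units where the species is absent everywhere carry occupancy 0 and
    missing (NaN) local means.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")
    keys = (["species", "year"] if scale == "regional_temporal"
            else ["species", "basin_id", "year"])
    if station_table.empty:
        raise ValueError("empty station table")

    g = station_table.groupby(keys, sort=True)
    summ = g.agg(n_stations=("present", "size"),
                 n_present=("present", "sum")).reset_index()
    if (summ["n_stations"] == 0).any():
        raise ValueError("analysis unit with zero visited stations")

    occupied = station_table[station_table["present"] == 1]
    means = (occupied.groupby(keys, sort=True)
             .agg(local_mean_abundance=("abundance", "mean"),
                  local_mean_biomass=("biomass", "mean")).reset_index())
    summ = summ.merge(means, on=keys, how="left")
    summ["occupancy"] = summ["n_present"] / summ["n_stations"]
    summ["scale"] = scale
    if scale == "regional_temporal":
        summ.insert(1, "basin_id", pd.NA)
    cols = ["species", "scale", "basin_id", "year", "local_mean_abundance",
            "local_mean_biomass", "occupancy", "n_stations", "n_present"]
    return summ[cols]


def all_scale_summaries(station_table: pd.DataFrame) -> pd.DataFrame:
    """Regional and basin-year summaries stacked in one table.

    The basin-year rows serve both the local-temporal and the spatial scale;
    they are computed once and labelled ``local_temporal`` (the regression
    stage regroups them per year for the spatial view).
    """
    return pd.concat([scale_summaries(station_table, "regional_temporal"),
                      scale_summaries(station_table, "local_temporal")],
                     ignore_index=True)


def basin_inclusion_filter(local_summaries: pd.DataFrame, min_years: int = 6,
                           n_years: int | None = None) -> pd.DataFrame:
    """(species, basin) pairs seen in at least ``min_years`` campaigns.

    A basin-year in which the species was present at least once counts as an
    observation year; basin-years that were never sampled are simply absent
    from the summaries and count toward neither side.  ``n_years`` is
    accepted for interface symmetry (the default rule is 6 of 8) but only
    ``min_years`` enters the decision.
    """
    loc = local_summaries[local_summaries["scale"] == "local_temporal"] \
        if "scale" in local_summaries.columns else local_summaries
    obs = (loc.assign(observed=(loc["n_present"] > 0).astype(int))
           .groupby(["species", "basin_id"])["observed"].sum().reset_index())
    keep = obs[obs["observed"] >= min_years][["species", "basin_id"]]
    logger.info("basin inclusion filter (>=%d years): kept %d of %d "
                "(species, basin) pairs", min_years, len(keep), len(obs))
    return keep.reset_index(drop=True)
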