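"""Synthetic gridded benthic survey generator.

Emulates a synoptic intertidal monitoring design of the SIBES type: sampling
stations laid out on a regular 0.5-km grid over the tidal flats of a set of
tidal basins, with 15--20% additional stations placed at random on the
gridlines, visited in yearly summer campaigns.  At every station a fixed
sediment surface (two cores of 1/112 m2 by default) is sampled and every
macrozoobenthic individual is identified, counted, and weighed (ash-free dry
mass of the flesh, AFDM, in grams).

Counts per station are drawn from a negative-binomial distribution with mean
``mu * area`` and aggregation parameter ``k`` (Poisson in the limit
``k = inf``), which is the standard model for spatially clumped benthic
counts: small ``k`` means strong clumping and hence low occupancy at a given
mean density.  Individual masses follow a power-law (allometric) length-mass
relation ``m = a * L**b`` with multiplicative lognormal noise.  A small
fraction of individuals receives a gross mass error (default x100) to
exercise downstream quality control, and known fractions of records lack a
mass or lack every measurement, mimicking laboratory bookkeeping losses.

Because every draw is governed by a single seeded generator, the module also
provides closed-form oracles (`theoretical_occupancy`,
`theoretical_aor_slope`) against which the downstream aggregation and
regression stages can be validated.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: total sampled surface per station: two cores of 1/112 m2 each
DEFAULT_CORE_AREA_M2 = 2.0 / 112.0

MEASUREMENT_KINDS = ("length", "size_class", "none")


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Basin:
    """Rectangular tidal-basin extent on which the station grid is laid."""

    basin_id: str
    width_km: float
    height_km: float
    x0_km: float = 0.0
    y0_km: float = 0.0
    #: fraction of grid nodes that fall on intertidal flats and are sampled
    intertidal_fraction: float = 1.0

    def validate(self) -> None:
        if self.width_km <= 0 or self.height_km <= 0:
            raise ValueError(f"basin {self.basin_id}: non-positive extent")
        if not 0 < self.intertidal_fraction <= 1:
            raise ValueError(f"basin {self.basin_id}: intertidal_fraction not in (0,1]")


@dataclass(frozen=True)
class SpeciesTruth:
    """Ground-truth parameters of one simulated species.

    Parameters
    ----------
    mu:
        True mean density (individuals m-2).  A scalar applies to every
        year and basin; a 1-d array of length ``n_years`` applies per year;
        a 2-d array of shape ``(n_years, n_basins)`` gives full control.
    k:
        Negative-binomial aggregation parameter; ``math.inf`` gives Poisson
        counts.  Smaller ``k`` = more clumped.
    length_median_mm, length_sigma:
        Median and lognormal sigma (natural log) of individual length.
    allometry_a, allometry_b:
        Coefficients of the length-mass power law ``m = a * L**b`` (g, mm).
    mass_cv:
        Sigma (natural log) of the multiplicative lognormal mass noise.
    measurement:
        Which size measurement ends up in the records: ``"length"``
        (bivalve style; shell length recorded), ``"size_class"``
        (polychaete style; only a juvenile/adult class recorded) or
        ``"none"`` (no size information recorded at all).
    size_class_threshold_mm:
        Length at or above which an individual is classed as adult
        (``measurement == "size_class"`` only).
    flesh_fraction:
        Proportion of the measured mass that is flesh.  1.0 for species whose
        flesh is weighed directly; 0.17 for gastropod-style species whose
        shell cannot be separated, in which case the generator records flesh
        mass directly (fraction already applied).
    p_zero:
        Zero-inflation probability: fraction of stations that are structural
        zeros regardless of density (emulates unsuitable habitat for rare,
        patchy species).
    """

    name: str
    mu: float | Sequence[float] | np.ndarray
    k: float = 1.0
    length_median_mm: float = 15.0
    length_sigma: float = 0.3
    allometry_a: float = 1e-5
    allometry_b: float = 3.0
    mass_cv: float = 0.2
    measurement: str = "length"
    size_class_threshold_mm: float | None = None
    flesh_fraction: float = 1.0
    p_zero: float = 0.0

    def validate(self) -> None:
        if np.any(np.asarray(self.mu, dtype=float) < 0):
            raise ValueError(f"species {self.name}: negative density")
        if not (self.k > 0 or math.isinf(self.k)):
            raise ValueError(f"species {self.name}: k must be > 0 or inf")
        if self.allometry_a <= 0 or self.allometry_b <= 0:
            raise ValueError(f"species {self.name}: non-positive allometry")
        if not 0 < self.flesh_fraction <= 1:
            raise ValueError(f"species {self.name}: flesh_fraction not in (0,1]")
        if self.measurement not in MEASUREMENT_KINDS:
            raise ValueError(f"species {self.name}: unknown measurement kind")
        if self.measurement == "size_class" and self.size_class_threshold_mm is None:
            raise ValueError(f"species {self.name}: size_class needs a threshold")
        if not 0 <= self.p_zero < 1:
            raise ValueError(f"species {self.name}: p_zero not in [0,1)")

    def mu_array(self, n_years: int, n_basins: int) -> np.ndarray:
        """Resolve ``mu`` to a dense (n_years, n_basins) array."""
        mu = np.asarray(self.mu, dtype=float)
        if mu.ndim == 0:
            return np.full((n_years, n_basins), float(mu))
        if mu.ndim == 1:
            if mu.shape[0] != n_years:
                raise ValueError(f"species {self.name}: mu length != n_years")
            return np.repeat(mu[:, None], n_basins, axis=1)
        if mu.shape != (n_years, n_basins):
            raise ValueError(f"species {self.name}: mu shape != (n_years, n_basins)")
        return mu


@dataclass(frozen=True)
class MissingDesign:
    """Which station-years are missing from an otherwise complete design.

    ``absent_basin_years`` lists (basin_id, year) pairs that were not visited
    at all (the study system analogue: the easternmost estuary was not
    sampled in the first campaign).  ``subsampled_year`` marks one campaign
    in which only ``subsample_fraction`` of stations were processed (the
    analogue of a final year in which only part of the samples had been
    analysed).
    """

    absent_basin_years: tuple[tuple[str, int], ...] = ()
    subsampled_year: int | None = None
    subsample_fraction: float = 0.3

    def validate(self, basin_ids: Sequence[str], years: Sequence[int]) -> None:
        for basin_id, year in self.absent_basin_years:
            if basin_id not in basin_ids:
                raise ValueError(f"missing_design references unknown basin {basin_id!r}")
            if year not in years:
                raise ValueError(f"missing_design references unknown year {year}")
        if self.subsampled_year is not None and self.subsampled_year not in years:
            raise ValueError("missing_design subsampled_year outside campaign years")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction not in (0,1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of one synthetic survey."""

    basins: tuple[Basin, ...]
    species: tuple[SpeciesTruth, ...]
    n_years: int = 8
    first_year: int = 2008
    grid_spacing_km: float = 0.5
    random_fraction: float = 0.175
    core_area_m2: float = DEFAULT_CORE_AREA_M2
    missing_design: MissingDesign = field(default_factory=MissingDesign)
    outlier_rate: float = 0.01
    outlier_factor: float = 100.0
    missing_mass_rate: float = 0.02
    missing_all_rate: float = 0.009
    seed: int = 0

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(self.first_year + t for t in range(self.n_years))

    def validate(self) -> None:
        if not self.species:
            raise ValueError("empty species list")
        if not self.basins:
            raise ValueError("empty basin list")
        if self.grid_spacing_km <= 0:
            raise ValueError("grid_spacing_km must be > 0")
        if not 0 <= self.random_fraction <= 1:
            raise ValueError("random_fraction not in [0,1]")
        if self.core_area_m2 <= 0:
            raise ValueError("core_area_m2 must be > 0")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate not in [0,1)")
        if self.outlier_rate + self.missing_mass_rate + self.missing_all_rate >= 1:
            raise ValueError("outlier/missing rates sum to >= 1")
        ids = [b.basin_id for b in self.basins]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate basin ids")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        for b in self.basins:
            b.validate()
        for s in self.species:
            s.validate()
            s.mu_array(self.n_years, len(self.basins))
        self.missing_design.validate(ids, self.years)


# ---------------------------------------------------------------------------
# closed-form oracles
# ---------------------------------------------------------------------------

def theoretical_occupancy(mu, k, area):
    """Presence probability of a negative-binomial count at one station.

    For counts with mean ``mu * area`` and aggregation ``k`` the probability
    of a non-zero count is ``1 - (1 + mu*area/k)**(-k)``; in the Poisson
    limit (``k = inf``) it is ``1 - exp(-mu*area)``.  Vectorised over ``mu``.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("negative density")
    if area <= 0:
        raise ValueError("non-positive area")
    if math.isinf(k):
        out = -np.expm1(-mu * area)
    else:
        if not k > 0:
            raise ValueError("k must be > 0 or inf")
        # 1 - (1 + mu*area/k)^(-k), computed in log space for stability
        out = -np.expm1(-k * np.log1p(mu * area / k))
    return out if out.ndim else float(out)


def theoretical_aor_slope(mu_grid, k, area) -> float:
    """Expected abundance-occupancy regression slope for a density gradient.

    For each true density ``mu`` the expected occupancy follows
    `theoretical_occupancy` and the expected local mean density (the mean
    over occupied stations only) is ``mu / occupancy``, because
    ``E[count | count > 0] = mu * area / P(count > 0)`` holds exactly for any
    count distribution.  The returned value is the OLS slope of
    ``log10(local mean density)`` on ``logit(occupancy)`` across the grid --
    the large-sample target of the regional abundance-occupancy regression.
    """
    mu = np.asarray(mu_grid, dtype=float)
    if mu.ndim != 1 or mu.size < 3:
        raise ValueError("mu_grid must be 1-d with at least 3 points")
    if np.any(mu <= 0):
        raise ValueError("mu_grid must be strictly positive")
    if np.unique(mu).size < 2:
        raise ValueError("degenerate regression: all densities equal")
    occ = theoretical_occupancy(mu, k, area)
    if np.any(occ <= 0) or np.any(occ >= 1):
        raise ValueError("occupancy of 0 or 1 on the grid")
    local_mean = mu / occ
    x = np.log(occ / (1 - occ))
    y = np.log10(local_mean)
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


# ---------------------------------------------------------------------------
# survey generation
# ---------------------------------------------------------------------------

def _basin_stations(basin: Basin, spacing: float, random_fraction: float,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Grid stations (both extent edges inclusive) plus random gridline extras."""
    nx = int(math.floor(basin.width_km / spacing + 1e-9)) + 1
    ny = int(math.floor(basin.height_km / spacing + 1e-9)) + 1
    gx, gy = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing,
                         indexing="ij")
    x = basin.x0_km + gx.ravel()
    y = basin.y0_km + gy.ravel()
    if basin.intertidal_fraction < 1.0:
        keep = rng.random(x.size) < basin.intertidal_fraction
        x, y = x[keep], y[keep]
    n_grid = x.size
    ids = [f"{basin.basin_id}-G{i:05d}" for i in range(n_grid)]

    n_extra = int(round(random_fraction * n_grid))
    if n_extra:
        vertical = rng.random(n_extra) < 0.5
        line = rng.integers(0, np.where(vertical, nx, ny))
        along = rng.random(n_extra)
        ex = np.where(vertical, line * spacing, along * basin.width_km)
        ey = np.where(vertical, along * basin.height_km, line * spacing)
        x = np.concatenate([x, basin.x0_km + ex])
        y = np.concatenate([y, basin.y0_km + ey])
        ids += [f"{basin.basin_id}-R{i:04d}" for i in range(n_extra)]
    return pd.DataFrame({"station_id": ids, "basin_id": basin.basin_id,
                         "x_km": x, "y_km": y})


def generate_survey(config: SyntheticConfig):
    """Generate one synthetic survey.

    Returns
    -------
    stations : DataFrame
        One row per sampling event (station x year):
        station_id, year, basin_id, x_km, y_km, area_m2.
    individuals : DataFrame
        One row per individual: station_id, year, species, length_mm,
        size_class, afdm_g, is_outlier_truth.
    truth : DataFrame
        Generator truth per species x year x basin: mu, k, p_zero, whether
        the basin-year was sampled, the theoretical occupancy and the
        theoretical local mean density.

    Notes
    -----
    All randomness comes from one ``numpy.random.default_rng(config.seed)``
    stream, consumed in a fixed order: station geometry (per basin, config
    order), the subsampled-year station selection, then per year (ascending)
    and species (config order) the station counts, lengths, mass noise and
    the outlier/missing assignment.  Identical configs and seeds therefore
    yield identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    basin_ids = [b.basin_id for b in config.basins]
    years = config.years

    site_frames = [_basin_stations(b, config.grid_spacing_km,
                                   config.random_fraction, rng)
                   for b in config.basins]
    sites = pd.concat(site_frames, ignore_index=True)

    md = config.missing_design
    subsample_keep: pd.Index | None = None
    if md.subsampled_year is not None:
        n_keep = int(round(md.subsample_fraction * len(sites)))
        keep_pos = rng.choice(len(sites), size=n_keep, replace=False)
        subsample_keep = sites.index[np.sort(keep_pos)]

    absent = set(md.absent_basin_years)
    station_frames = []
    for year in years:
        visited = sites
        if subsample_keep is not None and year == md.subsampled_year:
            visited = sites.loc[subsample_keep]
        visited = visited[~visited["basin_id"].map(
            lambda b, y=year: (b, y) in absent)]
        sf = visited.copy()
        sf.insert(1, "year", year)
        station_frames.append(sf)
    stations = pd.concat(station_frames, ignore_index=True)
    stations["area_m2"] = config.core_area_m2

    n_basins = len(config.basins)
    basin_pos = {b: i for i, b in enumerate(basin_ids)}
    mu_by_species = {s.name: s.mu_array(config.n_years, n_basins)
                     for s in config.species}

    ind_parts = []
    for t, year in enumerate(years):
        st_year = stations[stations["year"] == year]
        bidx = st_year["basin_id"].map(basin_pos).to_numpy()
        for sp in config.species:
            mean = mu_by_species[sp.name][t, bidx] * config.core_area_m2
            if math.isinf(sp.k):
                counts = rng.poisson(mean)
            else:
                p = sp.k / (sp.k + mean)
                counts = rng.negative_binomial(sp.k, p)
            if sp.p_zero > 0:
                counts = np.where(rng.random(counts.size) < sp.p_zero, 0, counts)
            n_ind = int(counts.sum())
            if n_ind == 0:
                continue
            st_ids = np.repeat(st_year["station_id"].to_numpy(), counts)
            length = rng.lognormal(math.log(sp.length_median_mm),
                                   sp.length_sigma, n_ind)
            mass = (sp.flesh_fraction * sp.allometry_a * length ** sp.allometry_b
                    * rng.lognormal(0.0, sp.mass_cv, n_ind))
            u = rng.random(n_ind)
            is_outlier = u < config.outlier_rate
            lo = config.outlier_rate
            missing_all = (u >= lo) & (u < lo + config.missing_all_rate)
            lo += config.missing_all_rate
            missing_mass = (u >= lo) & (u < lo + config.missing_mass_rate)
            mass = np.where(is_outlier, mass * config.outlier_factor, mass)
            afdm = np.where(missing_all | missing_mass, np.nan, mass)

            if sp.measurement == "length":
                length_out = np.where(missing_all, np.nan, length)
                size_class = np.full(n_ind, None, dtype=object)
            elif sp.measurement == "size_class":
                length_out = np.full(n_ind, np.nan)
                size_class = np.where(length >= sp.size_class_threshold_mm,
                                      "adult", "juvenile").astype(object)
                size_class[missing_all] = None
            else:
                length_out = np.full(n_ind, np.nan)
                size_class = np.full(n_ind, None, dtype=object)

            ind_parts.append(pd.DataFrame({
                "station_id": st_ids,
                "year": year,
                "species": sp.name,
                "length_mm": length_out,
                "size_class": size_class,
                "afdm_g": afdm,
                "is_outlier_truth": is_outlier,
            }))

    if ind_parts:
        individuals = pd.concat(ind_parts, ignore_index=True)
    else:
        individuals = pd.DataFrame(columns=[
            "station_id", "year", "species", "length_mm", "size_class",
            "afdm_g", "is_outlier_truth"])

    truth_rows = []
    for sp in config.species:
        mu_arr = mu_by_species[sp.name]
        for t, year in enumerate(years):
            for b, basin_id in enumerate(basin_ids):
                mu = mu_arr[t, b]
                occ = (1 - sp.p_zero) * theoretical_occupancy(
                    mu, sp.k, config.core_area_m2)
                truth_rows.append({
                    "species": sp.name, "year": year, "basin_id": basin_id,
                    "mu": mu, "k": sp.k, "p_zero": sp.p_zero,
                    "sampled": (basin_id, year) not in absent,
                    "occupancy_theory": occ,
                    "local_mean_density_theory":
                        mu / occ * (1 - sp.p_zero) if occ > 0 else np.nan,
                })
    truth = pd.DataFrame(truth_rows)
    logger.info("generated survey: %d station-years, %d individuals",
                len(stations), len(individuals))
    return stations, individuals, truth


def write_survey(out_dir, stations: pd.DataFrame, individuals: pd.DataFrame,
                 truth: pd.DataFrame) -> dict:
    """Write the three survey tables as UTF-8 CSV; returns name->path."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("stations", stations), ("individuals", individuals),
                     ("truth", truth)):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# default study-system-like configuration
# ---------------------------------------------------------------------------

def _mu_trajectory(base: float, n_years: int, n_basins: int,
                   amplitude: float, phase: float,
                   basin_spread: float) -> np.ndarray:
    """Deterministic density surface: sinusoidal year trend x basin levels."""
    t = np.arange(n_years)
    year_factor = np.exp(amplitude * np.sin(2 * np.pi * t / n_years + phase))
    b = np.arange(n_basins)
    basin_factor = np.exp(basin_spread * np.cos(2 * np.pi * b / n_basins + phase))
    return base * year_factor[:, None] * basin_factor[None, :]


def default_config(seed: int = 0, n_years: int = 8,
                   scale: float = 1.0) -> SyntheticConfig:
    """A ten-basin, eight-campaign survey emulating the study design.

    Basin extents give roughly 1,150 stations per full campaign at the
    default ``scale=1.0`` (a down-scaled but structurally faithful version
    of the real monitoring programme; pass ``scale=2.0`` to double linear
    extents).  The first campaign misses the easternmost basin and the last
    campaign is subsampled to 30% of stations.  Species parameters span the
    taxon styles of the study community: bivalves with measured shell
    lengths, polychaetes with juvenile/adult size classes, one species with
    no size information, one gastropod-style species whose recorded mass is
    17% flesh, and one rare zero-inflated species.
    """
    extents = [  # (width, height) km, loosely proportional basin sizes
        (7.0, 5.5), (4.0, 3.5), (7.5, 6.0), (5.0, 4.0), (3.0, 2.5),
        (5.5, 4.5), (2.5, 2.0), (4.0, 3.0), (2.0, 2.0), (6.0, 4.5),
    ]
    basins = []
    x0 = 0.0
    for i, (w, h) in enumerate(extents):
        basins.append(Basin(basin_id=f"B{i + 1:02d}", width_km=w * scale,
                            height_km=h * scale, x0_km=x0))
        x0 += w * scale + 2.0

    nb = len(basins)

    def traj(base, amp, phase, spread=0.5):
        return _mu_trajectory(base, n_years, nb, amp, phase, spread)

    species = (
        SpeciesTruth("cockle_like", traj(40.0, 0.9, 0.3), k=0.5,
                     length_median_mm=18, length_sigma=0.35,
                     allometry_a=8e-6, allometry_b=3.0, mass_cv=0.2),
        SpeciesTruth("tellinid_like", traj(70.0, 0.6, 1.7), k=0.8,
                     length_median_mm=12, length_sigma=0.3,
                     allometry_a=1.2e-5, allometry_b=2.9, mass_cv=0.2),
        SpeciesTruth("softshell_like", traj(12.0, 1.1, 3.1), k=0.3,
                     length_median_mm=25, length_sigma=0.5,
                     allometry_a=6e-6, allometry_b=3.1, mass_cv=0.25),
        SpeciesTruth("orbiniid_like", traj(220.0, 0.5, 4.2), k=1.0,
                     length_median_mm=30, length_sigma=0.4,
                     allometry_a=2e-6, allometry_b=2.5, mass_cv=0.25,
                     measurement="size_class", size_class_threshold_mm=30.0),
        SpeciesTruth("nereidid_like", traj(26.0, 0.7, 5.3), k=0.7,
                     length_median_mm=40, length_sigma=0.45,
                     allometry_a=1.5e-6, allometry_b=2.6, mass_cv=0.3,
                     measurement="size_class", size_class_threshold_mm=40.0),
        SpeciesTruth("capitellid_like", traj(7.0, 0.8, 0.9), k=0.5,
                     length_median_mm=20, length_sigma=0.4,
                     allometry_a=1e-6, allometry_b=2.4, mass_cv=0.3,
                     measurement="none"),
        SpeciesTruth("mudsnail_like", traj(385.0, 0.8, 2.4), k=0.05,
                     length_median_mm=4, length_sigma=0.25,
                     allometry_a=1e-4, allometry_b=2.3, mass_cv=0.2,
                     measurement="none", flesh_fraction=0.17),
        SpeciesTruth("rare_bivalve_like", traj(2.0, 0.6, 1.1), k=0.3,
                     length_median_mm=10, length_sigma=0.3,
                     allometry_a=1e-5, allometry_b=2.8, mass_cv=0.2,
                     p_zero=0.3),
    )
    years = tuple(2008 + t for t in range(n_years))
    missing = MissingDesign(
        absent_basin_years=((basins[-1].basin_id, years[0]),),
        subsampled_year=years[-1], subsample_fraction=0.3)
    return SyntheticConfig(basins=tuple(basins), species=species,
                           n_years=n_years, first_year=years[0],
                           missing_design=missing, seed=seed)


def single_basin_config(mu, k: float = 1.0, n_stations: int = 4000,
                        seed: int = 0, outlier_rate: float = 0.0,
                        missing_mass_rate: float = 0.0,
                        missing_all_rate: float = 0.0,
                        **species_kwargs) -> SyntheticConfig:
    """One-basin, one-species survey with an exact grid-station count.

    Convenience builder for calibration and recovery experiments: the basin
    extent is chosen so the lattice has exactly ``n_stations`` nodes (no
    random extras), and ``mu`` may be a scalar (one campaign per entry of a
    scalar -> a single year) or a per-year sequence.
    """
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=float))
    n_years = mu_arr.size
    # factor n_stations into the most square nx * ny lattice
    nx = int(math.sqrt(n_stations))
    while n_stations % nx:
        nx -= 1
    ny = n_stations // nx
    if nx < 2:
        raise ValueError("n_stations must have a factor pair >= 2x2 "
                         "(pick a composite count)")
    spacing = 0.5
    basin = Basin("B01", width_km=(nx - 1) * spacing,
                  height_km=(ny - 1) * spacing)
    species = SpeciesTruth("focal", mu=mu_arr, k=k, **species_kwargs)
    return SyntheticConfig(basins=(basin,), species=(species,),
                           n_years=n_years, grid_spacing_km=spacing,
                           random_fraction=0.0, outlier_rate=outlier_rate,
                           missing_mass_rate=missing_mass_rate,
                           missing_all_rate=missing_all_rate, seed=seed)


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a SyntheticConfig from a plain (YAML-loadable) mapping."""
    d = dict(d)
    basins = tuple(Basin(**b) for b in d.pop("basins"))
    species = tuple(
        SpeciesTruth(**{**s, "mu": np.asarray(s["mu"], dtype=float)
                        if not np.isscalar(s["mu"]) else s["mu"],
                        "k": math.inf if s.get("k") in ("inf", None) else s.get("k", 1.0)})
        for s in d.pop("species"))
    md = d.pop("missing_design", None)
    missing = MissingDesign(
        absent_basin_years=tuple((b, y) for b, y in md.get("absent_basin_years", ())),
        subsampled_year=md.get("subsampled_year"),
        subsample_fraction=md.get("subsample_fraction", 0.3),
    ) if md else MissingDesign()
    return SyntheticConfig(basins=basins, species=species,
                           missing_design=missing, **d)


def config_to_dict(config: SyntheticConfig) -> dict:
    """Plain-dict (JSON/YAML-serialisable) form of a SyntheticConfig."""
    d = dataclasses.asdict(config)
    for s in d["species"]:
        mu = np.asarray(s["mu"])
        s["mu"] = mu.tolist() if mu.ndim else float(mu)
        if math.isinf(s["k"]):
            s["k"] = "inf"
    d["missing_design"]["absent_basin_years"] = [
        list(p) for p in d["missing_design"]["absent_basin_years"]]
    return d
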