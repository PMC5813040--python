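"""Intraspecific abundance- and biomass-occupancy regression models.

Within one species, the yearly (or basin-wise) local mean abundance or
biomass is regressed on occupancy after transforming both axes: the response
is log10-transformed, occupancy is logit-transformed (natural log of
p/(1-p)).  Analysis sets that contain zeros are adjusted before the
transforms: the smallest positive response in the set is added to every
response, and an occupancy of exactly 0 (or 1) is moved into the open
interval by adding (subtracting) half of one over that unit's number of
stations.

Fit quality is summarised by the coefficient of determination R^2 and the
root mean squared error in log10 units, which is back-transformed to a
percent prediction error::

    RMSE_bt = (10 ** RMSE - 1) * 100

so that RMSE_bt = 100% means observed and predicted responses differ by a
factor of two on average.  A relationship is classified *strong* when
R^2 > 0.5 and RMSE_bt < 50%, *weak* when R^2 <= 0.5 and RMSE_bt >= 50%, and
*mixed* otherwise (both comparisons strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .aggregate import basin_inclusion_filter

logger = logging.getLogger(__name__)

RESPONSES = ("abundance", "biomass")


class UnfittableGroupError(ValueError):
    """An analysis set that cannot be transformed or regressed."""


@dataclass(frozen=True)
class TransformSpec:
    """Provenance of the axis transforms applied to one analysis set."""

    response_adjust: float      #: amount added to every response (0 if no zeros)
    occupancy_adjust: float     #: largest 0.5/n adjustment applied (0 if none)
    n_zero_responses: int
    n_adjusted_occupancies: int


@dataclass(frozen=True)
class RelationshipFit:
    """One fitted occupancy relationship and its diagnostics."""

    species: str
    scale: str
    response: str
    group: str                   #: basin (local), year (spatial), "" (regional)
    intercept: float
    intercept_se: float
    slope: float
    slope_se: float
    r_squared: float             #: proportion in [0, 1]
    rmse: float                  #: log10 units
    rmse_bt: float               #: percent
    p_value: float
    n_points: int
    significant: bool
    strength: str
    transform: TransformSpec
    rmse_denominator: str = "n"

    def as_row(self) -> dict:
        row = asdict(self)
        t = row.pop("transform")
        row["response_adjust"] = t["response_adjust"]
        row["occupancy_adjust"] = t["occupancy_adjust"]
        row["status"] = "ok"
        return row


def transform_xy(occupancy, response, n_stations):
    """Transformed (x, y) pairs for one analysis set, plus provenance.

    Parameters are per analysis unit: occupancy fraction, response (local
    mean abundance or biomass; 0 where the species was absent), and the
    unit's number of visited stations (used for the occupancy adjustment).

    Returns ``(x, y, TransformSpec)`` with x = logit occupancy and
    y = log10 response.
    """
    occ = np.asarray(occupancy, dtype=float)
    resp = np.asarray(response, dtype=float)
    n = np.asarray(n_stations, dtype=float)
    if occ.size < 3:
        raise UnfittableGroupError(f"only {occ.size} units (need >= 3)")
    if np.any((occ < 0) | (occ > 1)) or np.any(~np.isfinite(occ)):
        raise ValueError("occupancies must lie in [0, 1]")
    if np.any(resp < 0) or np.any(~np.isfinite(resp)):
        raise ValueError("responses must be finite and >= 0")
    if np.any(n <= 0):
        raise ValueError("n_stations must be positive")

    n_zero = int(np.sum(resp == 0))
    if n_zero == resp.size:
        raise UnfittableGroupError("all responses zero")
    adjust = float(resp[resp > 0].min()) if n_zero else 0.0
    resp = resp + adjust

    at_zero = occ == 0
    at_one = occ == 1
    occ = occ.copy()
    occ[at_zero] += 0.5 / n[at_zero]
    occ[at_one] -= 0.5 / n[at_one]
    n_adj = int(at_zero.sum() + at_one.sum())
    occ_adjust = float(np.max(0.5 / n[at_zero | at_one])) if n_adj else 0.0

    if np.ptp(occ) == 0:
        raise UnfittableGroupError("constant occupancy (degenerate x)")

    x = np.log(occ / (1 - occ))
    y = np.log10(resp)
    return x, y, TransformSpec(response_adjust=adjust,
                               occupancy_adjust=occ_adjust,
                               n_zero_responses=n_zero,
                               n_adjusted_occupancies=n_adj)


def rmse_bt(rmse: float) -> float:
    """Back-transformed RMSE: ``(10**rmse - 1) * 100`` percent."""
    if rmse < 0:
        raise ValueError("rmse must be >= 0")
    return (10.0 ** rmse - 1.0) * 100.0


def classify_strength(r_squared: float, rmse_bt_pct: float) -> str:
    """strong / weak / mixed classification (strict 50%/50% boundaries)."""
    if not 0 <= r_squared <= 1:
        raise ValueError("r_squared must be a proportion in [0, 1]")
    big_r2 = r_squared > 0.5
    small_err = rmse_bt_pct < 50.0
    if big_r2 and small_err:
        return "strong"
    if not big_r2 and not small_err:
        return "weak"
    return "mixed"


def fit_relationship(x, y, *, species: str = "", scale: str = "",
                     response: str = "", group: str = "",
                     transform: TransformSpec | None = None,
                     alpha: float = 0.05,
                     rmse_denominator: str = "n") -> RelationshipFit:
    """OLS fit of y on x with the package's diagnostics.

    RMSE uses ``sqrt(SSR/n)`` by default (prediction-error reading); pass
    ``rmse_denominator="n-2"`` for the residual-standard-error convention.
    The slope p-value is the two-sided t-test; ``significant`` compares it
    with ``alpha``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise UnfittableGroupError(f"n = {n} < 3")
    if np.ptp(x) == 0:
        raise UnfittableGroupError("constant x (degenerate regression)")
    if rmse_denominator not in ("n", "n-2"):
        raise ValueError("rmse_denominator must be 'n' or 'n-2'")

    res = sm.OLS(y, sm.add_constant(x)).fit()
    ssr = float(res.ssr)
    sst = float(res.centered_tss)
    r2 = 1.0 if sst == 0 else float(res.rsquared)
    r2 = min(max(r2, 0.0), 1.0)
    denom = n if rmse_denominator == "n" else n - 2
    rmse = float(np.sqrt(ssr / denom))
    p = float(res.pvalues[1])
    if not np.isfinite(p):          # perfect fit: zero residual variance
        p = 0.0
    bt = rmse_bt(rmse)
    return RelationshipFit(
        species=species, scale=scale, response=response, group=group,
        intercept=float(res.params[0]), intercept_se=float(res.bse[0]),
        slope=float(res.params[1]), slope_se=float(res.bse[1]),
        r_squared=r2, rmse=rmse, rmse_bt=bt, p_value=p, n_points=int(n),
        significant=bool(p < alpha), strength=classify_strength(r2, bt),
        transform=transform or TransformSpec(0.0, 0.0, 0, 0),
        rmse_denominator=rmse_denominator)


def _skipped_row(species, scale, response, group, reason) -> dict:
    return {"species": species, "scale": scale, "response": response,
            "group": group, "status": f"skipped: {reason}",
            "n_points": 0}


def _fit_group(df: pd.DataFrame, species, scale, response, group,
               alpha, rmse_denominator) -> dict:
    resp = df[f"local_mean_{response}"].to_numpy(dtype=float)
    resp = np.where(df["n_present"].to_numpy() == 0, 0.0, resp)
    try:
        x, y, spec = transform_xy(df["occupancy"].to_numpy(dtype=float),
                                  resp, df["n_stations"].to_numpy(dtype=float))
        fit = fit_relationship(x, y, species=species, scale=scale,
                               response=response, group=group,
                               transform=spec, alpha=alpha,
                               rmse_denominator=rmse_denominator)
        return fit.as_row()
    except UnfittableGroupError as exc:
        logger.info("skipped %s / %s / %s / %s: %s",
                    species, scale, response, group, exc)
        return _skipped_row(species, scale, response, group, exc)


def run_all_scales(scale_summaries: pd.DataFrame,
                   scales=("regional_temporal", "local_temporal", "spatial"),
                   responses=RESPONSES, min_years: int = 6,
                   alpha: float = 0.05, rmse_denominator: str = "n"):
    """Fit every species' occupancy relationships at the requested scales.

    ``scale_summaries`` is the stacked table from
    :func:`aopipe.aggregate.all_scale_summaries` (regional rows plus
    basin-year rows; the spatial scale reuses the basin-year rows regrouped
    per year).  Local-temporal fits are restricted to (species, basin) pairs
    passing the >= ``min_years``-of-n inclusion filter.  Unfittable groups
    appear as rows with a ``status`` reason, never as silent drops.

    Returns ``(fits, summaries)``: one row per attempted fit, and the
    median/IQR summary across grouping units per species x scale x response.
    """
    unknown = set(scales) - {"regional_temporal", "local_temporal", "spatial"}
    if unknown:
        raise ValueError(f"unknown scales: {sorted(unknown)}")
    regional = scale_summaries[scale_summaries["scale"] == "regional_temporal"]
    local = scale_summaries[scale_summaries["scale"] == "local_temporal"]

    rows = []
    if "regional_temporal" in scales:
        for sp, grp in regional.groupby("species", sort=True):
            grp = grp.sort_values("year")
            for response in responses:
                rows.append(_fit_group(grp, sp, "regional_temporal", response,
                                       "", alpha, rmse_denominator))
    if "local_temporal" in scales:
        keep = basin_inclusion_filter(local, min_years=min_years)
        kept = local.merge(keep, on=["species", "basin_id"], how="inner")
        for (sp, basin), grp in kept.groupby(["species", "basin_id"], sort=True):
            grp = grp.sort_values("year")
            for response in responses:
                rows.append(_fit_group(grp, sp, "local_temporal", response,
                                       str(basin), alpha, rmse_denominator))
    if "spatial" in scales:
        for (sp, year), grp in local.groupby(["species", "year"], sort=True):
            grp = grp.sort_values("basin_id")
            for response in responses:
                rows.append(_fit_group(grp, sp, "spatial", response,
                                       str(year), alpha, rmse_denominator))

    fits = pd.DataFrame(rows)
    if "status" not in fits.columns:
        fits["status"] = "ok"
    fits["status"] = fits["status"].fillna("ok")
    summaries = summarize_fits(fits)
    return fits, summaries


_SUMMARY_STATS = ("intercept", "slope", "r_squared", "rmse_bt")


def summarize_fits(fits: pd.DataFrame,
                   by=("species", "scale", "response")) -> pd.DataFrame:
    """Median and IQR of fit statistics across grouping units.

    Uses the same linear-interpolation quantile convention as the QC stage.
    Skipped rows are excluded.  For the regional scale (a single fit per
    species and response) medians equal the fit and IQRs are zero.
    """
    ok = fits[fits["status"] == "ok"] if "status" in fits.columns else fits
    if ok.empty:
        return pd.DataFrame(columns=[*by, "n_fits"])
    rows = []
    for key, grp in ok.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        row["n_fits"] = len(grp)
        for stat in _SUMMARY_STATS:
            v = grp[stat].to_numpy(dtype=float)
            q25, q50, q75 = np.percentile(v, [25, 50, 75], method="linear")
            row[f"{stat}_median"] = q50
            row[f"{stat}_iqr"] = q75 - q25
        rows.append(row)
    return pd.DataFrame(rows)
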