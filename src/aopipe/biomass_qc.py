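"""Biomass quality control: outlier detection, imputation, flesh fraction.

Individual ash-free dry masses (AFDM, g) from a benthic survey contain gross
errors (weighing or transcription mistakes) and gaps.  QC proceeds per
species:

* species with measured lengths (bivalve style): a local (loess-type)
  regression of log10 mass on log10 length is fitted; records whose absolute
  log10 residual exceeds twice the inter-quartile range (IQR) of the
  residuals are flagged as outliers and their mass replaced by the curve
  prediction at their length; records lacking mass are imputed the same way.
* species with juvenile/adult size classes (polychaete style): residuals are
  taken from the mean log10 mass of the species x size class; flagged or
  missing masses are imputed as 10**(mean log10 mass of non-outlier records
  of that class), i.e. the geometric mean.
* species with no size information: as above but with a single species-level
  mean log10 mass.
* records with neither a mass nor a length/size class cannot be repaired and
  are removed (and counted in the QC report).

Gastropod-style species whose shell and flesh are weighed together get their
mass multiplied once by a configured flesh fraction (0.17 in the study
community) before QC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

QC_FLAGS = ("ok", "outlier_imputed", "imputed_missing", "removed")

#: quantile interpolation convention used for every IQR in the package
QUANTILE_METHOD = "linear"


def iqr(values) -> float:
    """Inter-quartile range with the linear-interpolation quantile rule."""
    v = np.asarray(values, dtype=float)
    q75, q25 = np.percentile(v, [75, 25], method=QUANTILE_METHOD)
    return float(q75 - q25)


# ---------------------------------------------------------------------------
# loess smoother
# ---------------------------------------------------------------------------

def _loess(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray,
           span: float, degree: int) -> np.ndarray:
    """Local polynomial (tricube-weighted) regression, no robustness passes.

    For each evaluation point the ``ceil(span*n)`` nearest x values get
    tricube weights on distance scaled by the bandwidth (the q-th smallest
    distance) and a weighted polynomial of the requested degree is fitted.
    Input order must not matter, so callers should pass value-sorted data.
    """
    n = x.size
    q = min(n, max(degree + 1, int(math.ceil(span * n))))
    out = np.empty(x_eval.size)
    for i, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        h = np.partition(d, q - 1)[q - 1]
        if h <= 0:
            out[i] = y[d == 0].mean()
            continue
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        m = w > 0
        xm, ym, wm = x[m], y[m], w[m]
        deg = min(degree, np.unique(xm).size - 1)
        if deg == 0:
            out[i] = float(np.average(ym, weights=wm))
        else:
            coef = np.polyfit(xm - x0, ym, deg, w=np.sqrt(wm))
            out[i] = float(coef[-1])
    return out


@dataclass
class LengthMassCurve:
    """Fitted log10 length -> log10 mass relation for one species.

    ``kind`` is ``"loess"`` (local quadratic regression, the default) or
    ``"powerlaw"`` (global log-log straight line, the fall-back when too few
    paired records exist).  Predictions outside the observed length range
    are clamped to the nearest endpoint (logged).
    """

    species: str
    kind: str
    span: float
    degree: int
    knots_x: np.ndarray = field(repr=False)
    knots_y: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    residual_iqr: float = 0.0
    n_fit: int = 0

    @property
    def x_min(self) -> float:
        return float(self.knots_x[0])

    @property
    def x_max(self) -> float:
        return float(self.knots_x[-1])

    def predict(self, log10_length) -> np.ndarray:
        """Predicted log10 mass; nearest-endpoint clamp outside the range."""
        xq = np.asarray(log10_length, dtype=float)
        n_out = int(np.sum((xq < self.x_min) | (xq > self.x_max)))
        if n_out:
            logger.warning("%s: %d lengths outside fitted range "
                           "[%.3f, %.3f]; nearest-endpoint extrapolation",
                           self.species, n_out, self.x_min, self.x_max)
        out = np.interp(np.clip(xq, self.x_min, self.x_max),
                        self.knots_x, self.knots_y)
        return out if out.ndim else float(out)


#: above this many distinct lengths the smoother is evaluated on a grid of
#: knots and interpolated, as standard loess implementations do
MAX_EXACT_KNOTS = 1000


def fit_length_mass_curve(records: pd.DataFrame, species: str | None = None,
                          span: float = 0.75, degree: int = 2,
                          min_paired: int = 30) -> LengthMassCurve:
    """Fit the allometric smoother for one species' paired records.

    ``records`` needs columns ``length_mm`` and ``afdm_g``; rows lacking
    either are ignored.  With fewer than ``min_paired`` usable rows the fit
    falls back to a global power law (log-log OLS), which is logged.
    """
    if species is None:
        species = str(records["species"].iloc[0]) if "species" in records else "?"
    m = records["length_mm"].notna() & records["afdm_g"].notna()
    m &= (records["length_mm"] > 0) & (records["afdm_g"] > 0)
    sub = records.loc[m]
    if len(sub) < max(3, degree + 1):
        raise ValueError(f"{species}: too few paired length-mass records "
                         f"({len(sub)}) to fit any curve")
    x = np.log10(sub["length_mm"].to_numpy(dtype=float))
    y = np.log10(sub["afdm_g"].to_numpy(dtype=float))
    # value-sort so results cannot depend on record order
    order = np.lexsort((y, x))
    xs, ys = x[order], y[order]

    if len(sub) < min_paired:
        logger.warning("%s: only %d paired records (<%d); falling back to "
                       "global power-law fit", species, len(sub), min_paired)
        slope, intercept = np.polyfit(xs, ys, 1)
        knots_x = np.array([xs[0], xs[-1]])
        knots_y = intercept + slope * knots_x
        kind = "powerlaw"
    else:
        knots_x = np.unique(xs)
        if knots_x.size > MAX_EXACT_KNOTS:
            knots_x = np.unique(np.quantile(
                xs, np.linspace(0, 1, MAX_EXACT_KNOTS), method=QUANTILE_METHOD))
        knots_y = _loess(xs, ys, knots_x, span=span, degree=degree)
        kind = "loess"

    fitted = np.interp(x, knots_x, knots_y)
    resid = y - fitted
    out = np.full(len(records), np.nan)
    out[np.flatnonzero(m.to_numpy())] = resid
    return LengthMassCurve(species=species, kind=kind, span=span,
                           degree=degree, knots_x=knots_x, knots_y=knots_y,
                           residuals=out, residual_iqr=iqr(resid),
                           n_fit=len(sub))


@dataclass
class ClassMassReference:
    """Mean log10 mass per size class (or per species when classless)."""

    species: str
    class_means: dict
    residual_iqr: float
    residuals: np.ndarray = field(repr=False)

    def predict(self, size_class) -> float:
        key = size_class if size_class in self.class_means else None
        if key not in self.class_means:
            raise KeyError(f"{self.species}: no reference mass for class "
                           f"{size_class!r}")
        return self.class_means[key]


def fit_class_mass_reference(records: pd.DataFrame, species: str | None = None,
                             use_classes: bool = True,
                             exclude: np.ndarray | None = None) -> ClassMassReference:
    """Mean log10 mass per size class, from records with a measured mass.

    ``exclude`` (boolean mask aligned with ``records``) drops rows — used to
    recompute imputation means without flagged outliers.  Means are computed
    on value-sorted data for record-order independence.
    """
    if species is None:
        species = str(records["species"].iloc[0]) if "species" in records else "?"
    m = records["afdm_g"].notna() & (records["afdm_g"] > 0)
    if exclude is not None:
        m &= ~pd.Series(exclude, index=records.index)
    sub = records.loc[m]
    if sub.empty:
        raise ValueError(f"{species}: no measured masses to build a reference")
    logm = np.log10(sub["afdm_g"].to_numpy(dtype=float))
    means: dict = {}
    if use_classes and "size_class" in sub and sub["size_class"].notna().any():
        for cls, grp in sub.assign(_lm=logm).groupby("size_class", dropna=True):
            means[cls] = float(np.sort(grp["_lm"].to_numpy()).mean())
    means[None] = float(np.sort(logm).mean())

    keys = sub["size_class"] if "size_class" in sub else pd.Series(None, index=sub.index)
    pred = np.array([means.get(c if c in means else None) for c in keys])
    resid_sub = logm - pred
    resid = np.full(len(records), np.nan)
    resid[np.flatnonzero(m.to_numpy())] = resid_sub
    return ClassMassReference(species=species, class_means=means,
                              residual_iqr=iqr(resid_sub), residuals=resid)


# ---------------------------------------------------------------------------
# flagging and imputation
# ---------------------------------------------------------------------------

def flag_outliers(records: pd.DataFrame, curve, iqr_multiplier: float = 2.0
                  ) -> pd.Series:
    """Two-sided IQR rule: flag iff |log10 residual| > multiplier x IQR.

    Strict inequality: a residual exactly at the threshold is kept.  Records
    without the measurements the reference needs (mass, plus length for a
    length-mass curve) cannot be flagged and get False.
    """
    if iqr_multiplier <= 0:
        raise ValueError("iqr_multiplier must be > 0")
    if isinstance(curve, LengthMassCurve):
        usable = (records["afdm_g"].notna() & records["length_mm"].notna()
                  & (records["afdm_g"] > 0) & (records["length_mm"] > 0))
        resid = np.full(len(records), np.nan)
        u = usable.to_numpy()
        resid[u] = (np.log10(records.loc[usable, "afdm_g"].to_numpy(dtype=float))
                    - curve.predict(np.log10(
                        records.loc[usable, "length_mm"].to_numpy(dtype=float))))
    else:
        usable = records["afdm_g"].notna() & (records["afdm_g"] > 0)
        resid = np.full(len(records), np.nan)
        keys = (records["size_class"] if "size_class" in records
                else pd.Series(None, index=records.index))
        pred = np.array([curve.class_means.get(
            c if c in curve.class_means else None, np.nan) for c in keys])
        u = usable.to_numpy()
        resid[u] = np.log10(records.loc[usable, "afdm_g"].to_numpy(dtype=float)) - pred[u]
    # tiny absolute floor so float dust is never flagged when the fit is
    # exact and the residual IQR collapses to ~0
    threshold = iqr_multiplier * curve.residual_iqr + 1e-10
    with np.errstate(invalid="ignore"):
        flags = np.abs(resid) > threshold
    flags[~np.isfinite(resid)] = False
    return pd.Series(flags, index=records.index, name="is_outlier")


def impute_afdm(record: Mapping, curve=None, class_reference: ClassMassReference | None = None
                ) -> float:
    """Imputed mass (g) for one record; NaN if nothing can be imputed.

    Bivalve path: 10**(curve prediction at the record's log10 length).
    Size-class / classless path: 10**(mean log10 mass of non-outlier records
    of the class / species), i.e. the geometric mean.
    """
    length = record.get("length_mm")
    if curve is not None and length is not None and np.isfinite(length) and length > 0:
        return float(10.0 ** curve.predict(np.log10(float(length))))
    if class_reference is not None:
        cls = record.get("size_class")
        if cls is not None and not (isinstance(cls, float) and math.isnan(cls)):
            return float(10.0 ** class_reference.predict(cls))
        if None in class_reference.class_means:
            return float(10.0 ** class_reference.class_means[None])
    return float("nan")


def apply_flesh_fraction(afdm_g: float, flesh_fraction: float) -> float:
    """Flesh mass from a combined shell+flesh mass: ``afdm_g * fraction``."""
    if not 0 < flesh_fraction <= 1:
        raise ValueError("flesh_fraction must be in (0, 1]")
    return afdm_g * flesh_fraction


def apply_flesh_fraction_table(individuals: pd.DataFrame,
                               fractions: Mapping[str, float]) -> pd.DataFrame:
    """Apply species flesh fractions once to a whole individuals table.

    A table-level marker (``df.attrs['flesh_fraction_applied']``) prevents a
    second application.
    """
    done = set(individuals.attrs.get("flesh_fraction_applied", ()))
    out = individuals.copy()
    out.attrs = dict(individuals.attrs)
    applied = set(done)
    for sp, frac in fractions.items():
        if frac == 1.0:
            continue
        if sp in done:
            raise ValueError(f"flesh fraction already applied for {sp!r}")
        if not 0 < frac <= 1:
            raise ValueError(f"{sp}: flesh_fraction must be in (0, 1]")
        m = out["species"] == sp
        out.loc[m, "afdm_g"] = out.loc[m, "afdm_g"] * frac
        applied.add(sp)
    out.attrs["flesh_fraction_applied"] = sorted(applied)
    return out


# ---------------------------------------------------------------------------
# full QC pass
# ---------------------------------------------------------------------------

def _species_measurement(records: pd.DataFrame) -> str:
    if records["length_mm"].notna().any():
        return "length"
    if "size_class" in records and records["size_class"].notna().any():
        return "size_class"
    return "none"


def run_qc(individuals: pd.DataFrame,
           measurement_by_species: Mapping[str, str] | None = None,
           span: float = 0.75, degree: int = 2, iqr_multiplier: float = 2.0,
           min_paired: int = 30):
    """One QC pass over an individuals table.

    Adds ``afdm_g_clean`` and ``qc_flag`` columns (flags: ok,
    outlier_imputed, imputed_missing, removed) and returns
    ``(clean_table, qc_report)``.  The report has one row per species with
    record, flag, imputation and removal counts; the overall removed
    fraction is stored in ``report.attrs['removed_fraction']``.

    The pass is single (no re-fitting after outlier replacement); only the
    imputation means/curve targets exclude flagged records, per the
    imputation rules.
    """
    out = individuals.copy()
    out["afdm_g_clean"] = out["afdm_g"].astype(float)
    out["qc_flag"] = "ok"
    report_rows = []

    for sp, grp in out.groupby("species", sort=True):
        kind = (measurement_by_species or {}).get(sp) or _species_measurement(grp)
        has_mass = grp["afdm_g"].notna() & (grp["afdm_g"] > 0)
        has_len = grp["length_mm"].notna() & (grp["length_mm"] > 0)
        has_cls = (grp["size_class"].notna() if "size_class" in grp
                   else pd.Series(False, index=grp.index))

        flags = pd.Series(False, index=grp.index)
        curve = None
        ref = None
        if kind == "length":
            try:
                curve = fit_length_mass_curve(grp, species=sp, span=span,
                                              degree=degree, min_paired=min_paired)
                flags = flag_outliers(grp, curve, iqr_multiplier)
            except ValueError as exc:
                logger.warning("QC: %s", exc)
        else:
            try:
                ref_all = fit_class_mass_reference(grp, species=sp,
                                                   use_classes=(kind == "size_class"))
                flags = flag_outliers(grp, ref_all, iqr_multiplier)
            except ValueError as exc:
                logger.warning("QC: %s", exc)
        # imputation reference excludes flagged outliers
        if kind != "length":
            try:
                ref = fit_class_mass_reference(grp, species=sp,
                                               use_classes=(kind == "size_class"),
                                               exclude=flags.to_numpy())
            except ValueError:
                ref = None

        needs_value = flags | ~has_mass
        n_from_length = n_from_class = n_from_species_mean = n_removed = 0
        for idx in grp.index[needs_value]:
            rec_len = grp.at[idx, "length_mm"]
            rec_cls = grp.at[idx, "size_class"] if "size_class" in grp else None
            imputed = np.nan
            if curve is not None and has_len.at[idx]:
                imputed = 10.0 ** float(curve.predict(np.log10(float(rec_len))))
                n_from_length += 1
            elif ref is not None and has_cls.at[idx] and rec_cls in ref.class_means:
                imputed = 10.0 ** ref.class_means[rec_cls]
                n_from_class += 1
            elif ref is not None and kind == "none" and flags.at[idx]:
                # gross mass for a species with no size information: the only
                # usable reference is the species mean log10 mass
                imputed = 10.0 ** ref.class_means[None]
                n_from_species_mean += 1
            if np.isfinite(imputed):
                out.at[idx, "afdm_g_clean"] = imputed
                out.at[idx, "qc_flag"] = ("outlier_imputed" if flags.at[idx]
                                          else "imputed_missing")
            else:
                out.at[idx, "afdm_g_clean"] = np.nan
                out.at[idx, "qc_flag"] = "removed"
                n_removed += 1

        report_rows.append({
            "species": sp,
            "measurement": kind,
            "n_records": len(grp),
            "n_flagged_outliers": int(flags.sum()),
            "n_imputed_from_length": n_from_length,
            "n_imputed_from_size_class": n_from_class,
            "n_imputed_from_species_mean": n_from_species_mean,
            "n_removed": n_removed,
            "residual_iqr": (curve.residual_iqr if curve is not None
                             else ref.residual_iqr if ref is not None else np.nan),
            "curve_kind": (curve.kind if curve is not None
                           else "class_mean" if ref is not None else "none"),
        })

    report = pd.DataFrame(report_rows)
    n_total = int(report["n_records"].sum()) if len(report) else 0
    removed = int(report["n_removed"].sum()) if len(report) else 0
    report.attrs["removed_fraction"] = removed / n_total if n_total else 0.0
    logger.info("QC: %d records, %d outliers flagged, %d removed (%.2f%%)",
                n_total, int(report["n_flagged_outliers"].sum()) if len(report) else 0,
                removed, 100 * report.attrs["removed_fraction"])
    return out, report
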