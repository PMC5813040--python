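"""End-to-end pipeline: synth (or external tables) -> QC -> aggregate -> fit.

Every stage writes plain CSV into the run directory and the run closes with
a JSON manifest (package/library versions, seed, config, SHA-256 and row
count of every output) plus a human-readable report of the fitted
relationships and their strength classes.  Identical config and seed yield
byte-identical outputs and therefore identical manifest hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import aggregate, aor_models, biomass_qc, survey_synth

logger = logging.getLogger(__name__)

DEFAULT_SCALES = ("regional_temporal", "local_temporal", "spatial")


@dataclass
class RunConfig:
    """Settings for one pipeline run (YAML-loadable)."""

    out_dir: str = "aopipe_run"
    scales: tuple[str, ...] = DEFAULT_SCALES
    seed: int = 0
    # QC settings
    qc_span: float = 0.75
    qc_degree: int = 2
    qc_iqr_multiplier: float = 2.0
    qc_min_paired: int = 30
    # model settings
    alpha: float = 0.05
    rmse_denominator: str = "n"
    min_years: int = 6
    # input: synthetic generator config (dict form) or external CSV paths
    generator: dict | None = None
    external_stations: str | None = None
    external_individuals: str | None = None
    column_map: dict = field(default_factory=dict)
    flesh_fractions: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = set(self.scales) - set(DEFAULT_SCALES)
        if unknown:
            raise ValueError(f"unknown scales: {sorted(unknown)}")
        if self.qc_iqr_multiplier <= 0:
            raise ValueError("qc_iqr_multiplier must be > 0")
        if self.rmse_denominator not in ("n", "n-2"):
            raise ValueError("rmse_denominator must be 'n' or 'n-2'")
        external = self.external_stations or self.external_individuals
        if external and not (self.external_stations and self.external_individuals):
            raise ValueError("external runs need both stations and individuals paths")
        for p in (self.external_stations, self.external_individuals):
            if p and not Path(p).exists():
                raise ValueError(f"input file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**{k: tuple(v) if k == "scales" else v for k, v in data.items()})
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scales"] = list(self.scales)
        return d


REQUIRED_STATION_COLS = ("station_id", "year", "basin_id", "area_m2")
REQUIRED_INDIVIDUAL_COLS = ("station_id", "year", "species")
OPTIONAL_INDIVIDUAL_COLS = ("length_mm", "size_class", "afdm_g")


class SurveyValidationError(ValueError):
    """External survey tables failed validation; ``problems`` itemizes why."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("external survey validation failed:\n- "
                         + "\n- ".join(self.problems))


def read_external_survey(stations_path, individuals_path,
                         column_map: Mapping[str, str] | None = None):
    """Read and validate externally supplied survey CSVs.

    ``column_map`` maps external column names to the internal schema
    (e.g. ``{"sample_id": "station_id"}``).  All validation failures are
    collected and raised together as :class:`SurveyValidationError`.
    """
    column_map = dict(column_map or {})
    stations = pd.read_csv(stations_path).rename(columns=column_map)
    individuals = pd.read_csv(individuals_path).rename(columns=column_map)

    problems: list[str] = []
    for col in REQUIRED_STATION_COLS:
        if col not in stations.columns:
            problems.append(f"stations: missing required column {col!r}")
    for col in REQUIRED_INDIVIDUAL_COLS:
        if col not in individuals.columns:
            problems.append(f"individuals: missing required column {col!r}")
    if problems:
        raise SurveyValidationError(problems)

    for col in OPTIONAL_INDIVIDUAL_COLS:
        if col not in individuals.columns:
            individuals[col] = np.nan

    if not pd.api.types.is_numeric_dtype(stations["area_m2"]):
        problems.append("stations: area_m2 is not numeric "
                        "(mixed decimal conventions?)")
    elif (stations["area_m2"] <= 0).any():
        n = int((stations["area_m2"] <= 0).sum())
        problems.append(f"stations: {n} rows with non-positive area_m2")
    dup = stations.duplicated(["station_id", "year"])
    if dup.any():
        names = stations.loc[dup, ["station_id", "year"]].drop_duplicates()
        problems.append("stations: duplicated (station_id, year) rows: "
                        f"{names.head(5).to_dict('records')}")
    if "afdm_g" in individuals.columns and \
            pd.api.types.is_object_dtype(individuals["afdm_g"]):
        problems.append("individuals: afdm_g is not numeric "
                        "(mixed decimal conventions?)")
    key = pd.MultiIndex.from_frame(stations[["station_id", "year"]])
    ind_key = pd.MultiIndex.from_frame(individuals[["station_id", "year"]])
    orphans = ~ind_key.isin(key)
    if orphans.any():
        problems.append(f"individuals: {int(orphans.sum())} records reference "
                        "unknown station-years")
    blank = individuals["species"].isna()
    if blank.any():
        problems.append(f"individuals: {int(blank.sum())} records with empty species")
    if problems:
        raise SurveyValidationError(problems)
    return stations, individuals


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False)
    manifest["files"][path.name] = {"sha256": _sha256(path), "n_rows": len(df)}


def _report_text(fits: pd.DataFrame, summaries: pd.DataFrame) -> str:
    lines = ["Occupancy-relationship fits", "=" * 60]
    ok = fits[fits["status"] == "ok"]
    for scale, grp in ok.groupby("scale"):
        lines.append(f"\n[{scale}]  ({len(grp)} fits)")
        cols = ["species", "response", "group", "intercept", "slope",
                "r_squared", "rmse_bt", "p_value", "n_points", "strength"]
        sub = grp[cols].copy()
        for c in ("intercept", "slope", "r_squared"):
            sub[c] = sub[c].round(3)
        sub["rmse_bt"] = sub["rmse_bt"].round(1)
        sub["p_value"] = sub["p_value"].round(4)
        lines.append(sub.to_string(index=False))
    skipped = fits[fits["status"] != "ok"]
    if len(skipped):
        lines.append(f"\nSkipped groups: {len(skipped)}")
        lines.append(skipped[["species", "scale", "response", "group",
                              "status"]].to_string(index=False))
    if len(summaries):
        lines.append("\nMedian/IQR summaries across grouping units")
        lines.append(summaries.round(3).to_string(index=False))
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "aopipe_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "files": {},
        "stages": [],
    }

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s ...", name)
        manifest["stages"].append(name)
        return t0

    def done(name, t0):
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

    # --- input stage: synthetic survey or external tables -----------------
    measurement_by_species = None
    if config.external_stations:
        t0 = stage("read_external")
        stations, individuals = read_external_survey(
            config.external_stations, config.external_individuals,
            config.column_map)
        if config.flesh_fractions:
            individuals = biomass_qc.apply_flesh_fraction_table(
                individuals, config.flesh_fractions)
        done("read_external", t0)
    else:
        t0 = stage("synth")
        gen_cfg = (survey_synth.config_from_dict(config.generator)
                   if config.generator else survey_synth.default_config())
        gen_cfg = dataclasses.replace(gen_cfg, seed=config.seed)
        stations, individuals, truth = survey_synth.generate_survey(gen_cfg)
        measurement_by_species = {s.name: s.measurement for s in gen_cfg.species}
        manifest["generator"] = survey_synth.config_to_dict(gen_cfg)
        _write(truth, out / "truth.csv", manifest)
        done("synth", t0)
    _write(stations, out / "stations.csv", manifest)
    _write(individuals, out / "individuals.csv", manifest)

    # --- QC ----------------------------------------------------------------
    t0 = stage("qc")
    clean, qc_report = biomass_qc.run_qc(
        individuals, measurement_by_species, span=config.qc_span,
        degree=config.qc_degree, iqr_multiplier=config.qc_iqr_multiplier,
        min_paired=config.qc_min_paired)
    qc_report = qc_report.assign(
        removed_fraction_overall=qc_report.attrs.get("removed_fraction", 0.0))
    _write(clean, out / "individuals_clean.csv", manifest)
    _write(qc_report, out / "qc_report.csv", manifest)
    done("qc", t0)

    # --- aggregation ---------------------------------------------------------
    t0 = stage("aggregate")
    station_table = aggregate.station_summaries(stations, clean)
    summaries = aggregate.all_scale_summaries(station_table)
    _write(station_table, out / "station_summaries.csv", manifest)
    _write(summaries, out / "scale_summaries.csv", manifest)
    done("aggregate", t0)

    # --- model fits ----------------------------------------------------------
    t0 = stage("fit")
    fits, fit_summaries = aor_models.run_all_scales(
        summaries, scales=config.scales, min_years=config.min_years,
        alpha=config.alpha, rmse_denominator=config.rmse_denominator)
    _write(fits, out / "relationship_fits.csv", manifest)
    _write(fit_summaries, out / "fit_summaries.csv", manifest)
    report = _report_text(fits, fit_summaries)
    (out / "report.txt").write_text(report, encoding="utf-8")
    manifest["files"]["report.txt"] = {
        "sha256": _sha256(out / "report.txt"),
        "n_rows": report.count("\n")}
    done("fit", t0)

    skipped_scales = sorted(set(DEFAULT_SCALES) - set(config.scales))
    if skipped_scales:
        manifest["skipped_scales"] = skipped_scales
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run complete: %s", out)
    return manifest
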