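"""CSV/JSON schemas shared by the pipeline stages.

Chamber runs travel as a pair of CSVs: a long-format concentration table
(run_id, site, plot, date, replicate, elapsed_s, co2_ppm, ch4_ppm) and a
per-run metadata table (temperature, pressure, geometry). Meteorology and
water samples are single flat CSVs. All files are UTF-8 with a header row,
ISO-8601 dates, and empty fields (never sentinels) for missing values.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chamber import AnnualFlux, ChamberRun, FluxRecord

__all__ = [
    "write_chamber_csvs",
    "read_chamber_runs",
    "write_met_csv",
    "read_met_csv",
    "write_water_csv",
    "read_water_csv",
    "flux_records_frame",
    "annual_summary_frame",
    "write_json",
    "ValidationReport",
    "validate_inputs",
]

MET_COLUMNS = ["timestamp", "rain_mm", "tair_c", "rh_pct", "solar_w_m2", "wind_m_s"]
WATER_COLUMNS = [
    "date", "analyte", "doc_mg_l", "filter_dry_g", "filter_combusted_g",
    "volume_filtered_l", "water_ph", "water_temp_c",
]
SERIES_COLUMNS = ["run_id", "site", "plot", "date", "replicate", "elapsed_s", "co2_ppm", "ch4_ppm"]
META_COLUMNS = [
    "run_id", "site", "plot", "date", "replicate", "air_temp_k", "pressure_kpa",
    "chamber_volume_m3", "collar_area_m2",
]


def write_chamber_csvs(runs: Iterable[ChamberRun], series_path: Path, meta_path: Path) -> None:
    series_rows, meta_rows = [], []
    for run in runs:
        meta_rows.append({
            "run_id": run.run_id, "site": run.site, "plot": run.plot,
            "date": run.date.isoformat(), "replicate": run.replicate,
            "air_temp_k": run.air_temp_k, "pressure_kpa": run.pressure_kpa,
            "chamber_volume_m3": run.chamber_volume_m3, "collar_area_m2": run.collar_area_m2,
        })
        series_rows.append(pd.DataFrame({
            "run_id": run.run_id, "site": run.site, "plot": run.plot,
            "date": run.date.isoformat(), "replicate": run.replicate,
            "elapsed_s": run.elapsed_s, "co2_ppm": run.co2_ppm, "ch4_ppm": run.ch4_ppm,
        }))
    pd.concat(series_rows, ignore_index=True).to_csv(series_path, index=False)
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)


def read_chamber_runs(series_path: Path, meta_path: Path) -> list[ChamberRun]:
    series = pd.read_csv(series_path)
    meta = pd.read_csv(meta_path).set_index("run_id")
    runs = []
    for run_id, grp in series.groupby("run_id", sort=False):
        m = meta.loc[run_id]
        runs.append(ChamberRun(
            run_id=str(run_id), site=str(m["site"]), plot=int(m["plot"]),
            date=dt.date.fromisoformat(str(m["date"])), replicate=int(m["replicate"]),
            elapsed_s=grp["elapsed_s"].to_numpy(float),
            co2_ppm=grp["co2_ppm"].to_numpy(float),
            ch4_ppm=grp["ch4_ppm"].to_numpy(float),
            air_temp_k=float(m["air_temp_k"]), pressure_kpa=float(m["pressure_kpa"]),
            chamber_volume_m3=float(m["chamber_volume_m3"]),
            collar_area_m2=float(m["collar_area_m2"]),
        ))
    return runs


def write_met_csv(met: pd.DataFrame, path: Path) -> None:
    met.to_csv(path, index=False, columns=MET_COLUMNS)


def read_met_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_water_csv(samples: pd.DataFrame, path: Path) -> None:
    samples.to_csv(path, index=False, columns=WATER_COLUMNS)


def read_water_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path)


def flux_records_frame(records: Sequence[FluxRecord]) -> pd.DataFrame:
    """Flux records with fit diagnostics and QC/outlier flags as a table."""
    return pd.DataFrame([
        {
            "run_id": r.run_id, "site": r.site, "plot": r.plot,
            "date": r.date.isoformat(), "replicate": r.replicate, "gas": r.gas,
            "flux_umol_m2_s": r.flux_umol_m2_s, "slope_ppm_s": r.fit.slope,
            "intercept_ppm": r.fit.intercept, "r_squared": r.fit.r_squared,
            "n_points": r.fit.n_points, "qc_pass": r.qc_pass, "outlier": r.outlier,
        }
        for r in records
    ])


def annual_summary_frame(annual: dict[tuple[str, str], AnnualFlux]) -> pd.DataFrame:
    """Annual site fluxes as a table (one row per site × gas)."""
    return pd.DataFrame([
        {
            "site": f.site, "gas": f.gas, "mean": f.mean, "se": f.se,
            "n": f.n, "units": f.units,
        }
        for f in annual.values()
    ])


def write_json(obj: dict, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _check_columns(df: pd.DataFrame, required: list[str], label: str, rep: ValidationReport) -> bool:
    missing = [c for c in required if c not in df.columns]
    if missing:
        rep.errors.append(f"{label}: missing column(s) {missing}")
        return False
    return True


def validate_inputs(
    chamber_series: Path | None = None,
    chamber_meta: Path | None = None,
    met: Path | None = None,
    water: Path | None = None,
) -> ValidationReport:
    """Schema, unit-range and monotonicity checks on the input CSVs.

    Errors are conditions the pipeline cannot compute through (bad schema,
    out-of-range physics, non-monotone time); warnings are recoverable
    oddities.
    """
    rep = ValidationReport()
    if chamber_series is not None:
        df = pd.read_csv(chamber_series)
        if _check_columns(df, SERIES_COLUMNS, "chamber series", rep):
            for run_id, grp in df.groupby("run_id", sort=False):
                t = grp["elapsed_s"].to_numpy(float)
                if np.any(np.diff(t) <= 0):
                    rep.errors.append(f"chamber series: non-monotone elapsed_s in run {run_id}")
            if df[["co2_ppm", "ch4_ppm"]].lt(0).any().any():
                rep.errors.append("chamber series: negative mole fraction")
    if chamber_meta is not None:
        df = pd.read_csv(chamber_meta)
        if _check_columns(df, META_COLUMNS, "chamber meta", rep):
            for col in ("air_temp_k", "pressure_kpa", "chamber_volume_m3", "collar_area_m2"):
                bad = df.index[df[col] <= 0].tolist()
                if bad:
                    rep.errors.append(f"chamber meta: non-positive {col} in row(s) {bad}")
    if met is not None:
        df = pd.read_csv(met)
        if _check_columns(df, MET_COLUMNS, "met", rep):
            bad_rh = df.index[(df["rh_pct"] < 0) | (df["rh_pct"] > 100)].tolist()
            if bad_rh:
                rep.errors.append(f"met: rh_pct outside [0, 100] in row(s) {bad_rh[:10]}")
            for col in ("rain_mm", "solar_w_m2", "wind_m_s"):
                bad = df.index[df[col] < 0].tolist()
                if bad:
                    rep.errors.append(f"met: negative {col} in row(s) {bad[:10]}")
    if water is not None:
        df = pd.read_csv(water)
        if _check_columns(df, WATER_COLUMNS, "water", rep):
            unknown = set(df["analyte"].unique()) - {"DOC", "POC"}
            if unknown:
                rep.errors.append(f"water: unknown analyte label(s) {sorted(unknown)}")
            poc = df[df["analyte"] == "POC"]
            if (poc["volume_filtered_l"] <= 0).any():
                rep.errors.append("water: non-positive filtered volume in a POC row")
            flagged = poc[poc["filter_dry_g"] < poc["filter_combusted_g"]]
            if len(flagged):
                rep.warnings.append(
                    f"water: combusted mass exceeds dry mass in {len(flagged)} POC row(s)"
                )
    return rep
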