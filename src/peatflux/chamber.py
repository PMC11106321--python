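"""Closed-chamber CO2/CH4 flux computation.

A chamber deployment yields a short concentration time series (mole fraction
vs. elapsed seconds). The flux is the initial rate of concentration change,
estimated by an ordinary least-squares line fitted after a dead band that
discards placement artifacts, converted to an areal molar flux with the ideal
gas law, quality-filtered on the fit R², screened for outliers, and averaged
up to annual site-level mass fluxes.

Aggregation follows the campaign design: the replicates of one plot on one
day are averaged first, so the annual statistics are computed over
plot-day values (n = plots × months × days per site for a complete,
fully-passing campaign).
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import (
    GASES,
    GWP100_CH4,
    R2_THRESHOLDS,
    R_GAS,
    SECONDS_PER_YEAR,
    umol_to_mg_ha_yr,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ChamberRun",
    "FitResult",
    "FluxRecord",
    "AnnualFlux",
    "FitError",
    "fit_linear_deadband",
    "slope_to_flux",
    "qc_filter",
    "process_runs",
    "screen_outliers",
    "aggregate_daily_plot",
    "annualize",
    "ch4_to_co2e",
    "landscape_mean",
    "site_total_co2e",
    "compute_annual_fluxes",
]


class FitError(ValueError):
    """Raised when a concentration series cannot support a regression."""


@dataclass
class ChamberRun:
    """One chamber deployment: a 2-minute concentration record plus the
    geometry and environment needed to turn a slope into a flux.

    ``chamber_volume_m3`` is the whole closed system (chamber + collar
    headspace + tubing); ``collar_area_m2`` is the soil/water surface
    enclosed by the collar.
    """

    run_id: str
    site: str
    plot: int
    date: dt.date
    replicate: int
    elapsed_s: np.ndarray
    co2_ppm: np.ndarray
    ch4_ppm: np.ndarray
    air_temp_k: float
    pressure_kpa: float
    chamber_volume_m3: float
    collar_area_m2: float
    # Latent ground truth, populated by the synthetic generator only
    # (µmol m⁻² s⁻¹); None for field data.
    true_flux_umol: dict | None = None
    # Synthetic bookkeeping: run was generated with a saturating (QC-failing)
    # concentration response.
    synthetic_qc_fail: bool = False

    def __post_init__(self) -> None:
        self.elapsed_s = np.asarray(self.elapsed_s, dtype=float)
        self.co2_ppm = np.asarray(self.co2_ppm, dtype=float)
        self.ch4_ppm = np.asarray(self.ch4_ppm, dtype=float)
        if self.elapsed_s.ndim != 1 or np.any(np.diff(self.elapsed_s) <= 0):
            raise ValueError(f"run {self.run_id}: elapsed_s must be strictly increasing")
        if len(self.co2_ppm) != len(self.elapsed_s) or len(self.ch4_ppm) != len(self.elapsed_s):
            raise ValueError(f"run {self.run_id}: series lengths differ")
        if not (self.air_temp_k > 0 and self.pressure_kpa > 0):
            raise ValueError(f"run {self.run_id}: temperature and pressure must be positive")
        if not (self.chamber_volume_m3 > 0 and self.collar_area_m2 > 0):
            raise ValueError(f"run {self.run_id}: chamber geometry must be positive")

    def series(self, gas: str) -> np.ndarray:
        if gas == "CO2":
            return self.co2_ppm
        if gas == "CH4":
            return self.ch4_ppm
        raise ValueError(f"unknown gas {gas!r}")


@dataclass(frozen=True)
class FitResult:
    """OLS line through the in-window samples of one gas on one run."""

    slope: float  # µmol mol⁻¹ s⁻¹
    intercept: float  # µmol mol⁻¹ (at t = 0)
    r_squared: float
    n_points: int
    window: tuple[float, float]  # (t_start, t_stop], seconds


@dataclass
class FluxRecord:
    """Fitted flux and QC verdict for one gas on one run."""

    run_id: str
    site: str
    plot: int
    date: dt.date
    replicate: int
    gas: str
    flux_umol_m2_s: float
    fit: FitResult
    qc_pass: bool
    outlier: bool = False


@dataclass(frozen=True)
class AnnualFlux:
    """Annual site-level mass flux: mean ± SE over plot-day values."""

    site: str
    gas: str
    mean: float
    se: float
    n: int
    units: str  # "MgCO2 ha-1 yr-1" | "MgCH4 ha-1 yr-1" | "MgCO2e ha-1 yr-1"


def fit_linear_deadband(
    elapsed_s: Sequence[float],
    conc: Sequence[float],
    deadband_s: float = 10.0,
    stop_s: float = 120.0,
) -> FitResult:
    """Ordinary least-squares line on the samples with deadband_s < t ≤ stop_s.

    The dead band discards the first seconds after chamber closure, when
    placement disturbance and incomplete mixing distort the record. R² for a
    zero-variance (constant) response is defined as 0 so that flat series
    deterministically fail QC.

    Raises
    ------
    FitError
        If fewer than 3 samples fall inside the window.
    """
    t = np.asarray(elapsed_s, dtype=float)
    y = np.asarray(conc, dtype=float)
    mask = (t > deadband_s) & (t <= stop_s)
    n = int(mask.sum())
    if n < 3:
        raise FitError(f"only {n} samples in window ({deadband_s}, {stop_s}]; need >= 3")
    tw, yw = t[mask], y[mask]
    tc = tw - tw.mean()
    sxx = float(tc @ tc)
    slope = float(tc @ (yw - yw.mean())) / sxx
    intercept = float(yw.mean() - slope * tw.mean())
    sst = float(((yw - yw.mean()) ** 2).sum())
    if sst == 0.0:
        r2 = 0.0  # constant-response convention
    else:
        resid = yw - (intercept + slope * tw)
        r2 = 1.0 - float((resid @ resid)) / sst
        r2 = min(max(r2, 0.0), 1.0)
    return FitResult(slope, intercept, r2, n, (deadband_s, stop_s))


def slope_to_flux(
    slope_ppm_s: float,
    air_temp_k: float,
    pressure_kpa: float,
    volume_m3: float,
    area_m2: float,
) -> float:
    """Convert a mole-fraction rate (µmol mol⁻¹ s⁻¹) to an areal molar flux
    (µmol m⁻² s⁻¹) with the ideal gas law.

    flux = slope · P·V / (R·T·A), with P in Pa: P·V/(R·T) is the moles of
    air enclosed, so slope × moles / area is the molar emission rate per
    unit soil surface.
    """
    if not (air_temp_k > 0 and pressure_kpa > 0 and volume_m3 > 0 and area_m2 > 0):
        raise ValueError("temperature, pressure, volume and area must be positive")
    mol_air = pressure_kpa * 1000.0 * volume_m3 / (R_GAS * air_temp_k)
    return slope_ppm_s * mol_air / area_m2


def qc_filter(record: FluxRecord, thresholds: Mapping[str, float] = R2_THRESHOLDS) -> bool:
    """True iff the record's fit R² is strictly above its gas's threshold."""
    if record.gas not in thresholds:
        raise ValueError(f"unknown gas {record.gas!r}")
    return record.fit.r_squared > thresholds[record.gas]


def process_runs(
    runs: Iterable[ChamberRun],
    deadband_s: float = 10.0,
    stop_s: float = 120.0,
    thresholds: Mapping[str, float] = R2_THRESHOLDS,
) -> list[FluxRecord]:
    """Fit, convert and QC every run for both gases.

    Runs whose window holds fewer than 3 samples are excluded and logged.
    """
    records: list[FluxRecord] = []
    for run in runs:
        for gas in GASES:
            try:
                fit = fit_linear_deadband(run.elapsed_s, run.series(gas), deadband_s, stop_s)
            except FitError as exc:
                logger.warning("run %s %s excluded: %s", run.run_id, gas, exc)
                continue
            flux = slope_to_flux(
                fit.slope, run.air_temp_k, run.pressure_kpa,
                run.chamber_volume_m3, run.collar_area_m2,
            )
            rec = FluxRecord(
                run.run_id, run.site, run.plot, run.date, run.replicate,
                gas, flux, fit, qc_pass=False,
            )
            rec.qc_pass = qc_filter(rec, thresholds)
            records.append(rec)
    return records


def screen_outliers(records: Sequence[FluxRecord], k: float = 3.0) -> list[FluxRecord]:
    """Flag fluxes outside median ± k·IQR within each site × gas × month group.

    Only QC-passing records participate; flagged records keep their data but
    are excluded downstream. Degenerate groups (IQR = 0, or fewer than 4
    passing records) flag nothing. Returns new records; inputs not mutated.
    """
    out = [replace(r) for r in records]
    groups: dict[tuple, list[FluxRecord]] = {}
    for r in out:
        if r.qc_pass:
            groups.setdefault((r.site, r.gas, r.date.year, r.date.month), []).append(r)
    for members in groups.values():
        if len(members) < 4 or not math.isfinite(k):
            continue
        values = np.array([m.flux_umol_m2_s for m in members])
        med = float(np.median(values))
        q25, q75 = np.percentile(values, [25, 75])
        iqr = float(q75 - q25)
        if iqr == 0.0:
            continue
        lo, hi = med - k * iqr, med + k * iqr
        for m in members:
            if not (lo <= m.flux_umol_m2_s <= hi):
                m.outlier = True
                logger.info("outlier flagged: %s %s %.4g", m.run_id, m.gas, m.flux_umol_m2_s)
    return out


def aggregate_daily_plot(records: Sequence[FluxRecord]) -> pd.DataFrame:
    """Average the replicates of each site × plot × date × gas to one value.

    Only QC-passing, non-flagged replicates contribute. A plot-day with zero
    passing replicates yields no row (logged); the number of contributing
    replicates is recorded.
    """
    rows = [
        {
            "site": r.site, "plot": r.plot, "date": r.date, "gas": r.gas,
            "flux_umol_m2_s": r.flux_umol_m2_s,
        }
        for r in records
        if r.qc_pass and not r.outlier
    ]
    all_keys = {(r.site, r.plot, r.date, r.gas) for r in records}
    if not rows:
        logger.warning("no passing replicates in %d records", len(records))
        return pd.DataFrame(columns=["site", "plot", "date", "gas", "flux_umol_m2_s", "n_replicates"])
    df = pd.DataFrame(rows)
    agg = (
        df.groupby(["site", "plot", "date", "gas"], as_index=False)
        .agg(flux_umol_m2_s=("flux_umol_m2_s", "mean"), n_replicates=("flux_umol_m2_s", "size"))
    )
    dropped = len(all_keys) - len(agg)
    if dropped > 0:
        logger.info("%d plot-day groups had no passing replicates", dropped)
    return agg


def annualize(
    daily_plot_fluxes: Sequence[float],
    gas: str,
    site: str = "",
    seconds_per_year: float = SECONDS_PER_YEAR,
) -> AnnualFlux:
    """Mean ± SE of the plot-day molar fluxes, converted to Mg gas ha⁻¹ yr⁻¹.

    SE = sd/√n over the plot-day values (the campaign's n = 360 per site for
    a complete year of 10 plots × 12 months × 3 days).
    """
    x = np.asarray(daily_plot_fluxes, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 plot-day fluxes for a standard error")
    factor = umol_to_mg_ha_yr(gas, seconds_per_year)
    mean = float(x.mean()) * factor
    se = float(x.std(ddof=1)) / math.sqrt(n) * factor
    units = f"Mg{gas} ha-1 yr-1"
    return AnnualFlux(site=site, gas=gas, mean=mean, se=se, n=n, units=units)


def ch4_to_co2e(ch4: AnnualFlux, gwp100: float = GWP100_CH4) -> AnnualFlux:
    """Express a CH4 mass flux as CO2-equivalent via the 100-year GWP."""
    if ch4.gas != "CH4":
        raise ValueError("ch4_to_co2e expects a CH4 flux")
    return AnnualFlux(
        site=ch4.site, gas="CH4", mean=ch4.mean * gwp100, se=ch4.se * gwp100,
        n=ch4.n, units="MgCO2e ha-1 yr-1",
    )


def landscape_mean(site_fluxes: Sequence[AnnualFlux], se_rule: str = "quadrature") -> AnnualFlux:
    """Landscape mean of ≥2 site-level annual fluxes for one gas.

    se_rule:
      * ``"quadrature"`` (default): √Σ seᵢ² — quadrature *sum* of site SEs.
      * ``"mean"``: √Σ seᵢ² / n — the conventional SE of a mean of
        independent site means.
    """
    if len(site_fluxes) < 2:
        raise ValueError("need at least 2 sites")
    gases = {f.gas for f in site_fluxes}
    units = {f.units for f in site_fluxes}
    if len(gases) != 1 or len(units) != 1:
        raise ValueError("site fluxes must share gas and units")
    means = np.array([f.mean for f in site_fluxes])
    quad = math.sqrt(sum(f.se**2 for f in site_fluxes))
    if se_rule == "quadrature":
        se = quad
    elif se_rule == "mean":
        se = quad / len(site_fluxes)
    else:
        raise ValueError(f"unknown se_rule {se_rule!r}")
    return AnnualFlux(
        site="landscape", gas=gases.pop(), mean=float(means.mean()), se=se,
        n=sum(f.n for f in site_fluxes), units=units.pop(),
    )


def site_total_co2e(co2: AnnualFlux, ch4_co2e: AnnualFlux) -> AnnualFlux:
    """Total greenhouse-gas flux of one site: CO2 + CH4-as-CO2e, SE in quadrature."""
    if co2.site != ch4_co2e.site:
        raise ValueError(f"site mismatch: {co2.site!r} vs {ch4_co2e.site!r}")
    if ch4_co2e.units != "MgCO2e ha-1 yr-1":
        raise ValueError("CH4 flux must be in CO2e units; apply ch4_to_co2e first")
    return AnnualFlux(
        site=co2.site, gas="total", mean=co2.mean + ch4_co2e.mean,
        se=math.hypot(co2.se, ch4_co2e.se), n=co2.n, units="MgCO2e ha-1 yr-1",
    )


def compute_annual_fluxes(
    runs: Iterable[ChamberRun],
    deadband_s: float = 10.0,
    stop_s: float = 120.0,
    thresholds: Mapping[str, float] = R2_THRESHOLDS,
    outlier_k: float = 3.0,
    seconds_per_year: float = SECONDS_PER_YEAR,
) -> tuple[dict[tuple[str, str], AnnualFlux], list[FluxRecord], pd.DataFrame]:
    """Full per-site chain: fit → gas-law flux → QC → outlier screen →
    plot-day means → annual mean ± SE.

    Returns (annual fluxes keyed by (site, gas), all flux records with QC and
    outlier flags, the plot-day table).
    """
    records = process_runs(runs, deadband_s, stop_s, thresholds)
    records = screen_outliers(records, outlier_k)
    daily = aggregate_daily_plot(records)
    annual: dict[tuple[str, str], AnnualFlux] = {}
    if daily.empty:
        return annual, records, daily
    for (site, gas), grp in daily.groupby(["site", "gas"]):
        annual[(site, gas)] = annualize(
            grp["flux_umol_m2_s"].to_numpy(), gas, site, seconds_per_year
        )
    return annual, records, daily
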