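"""FAO-56 Penman–Monteith reference evapotranspiration and the annual
catchment water balance.

Daily reference evapotranspiration (ET0) of the standardized grass surface:

    ET0 = [0.408·Δ·(Rn − G) + γ·(900/(T+273))·u2·(es − ea)]
          / [Δ + γ·(1 + 0.34·u2)]

with the standard FAO-56 component chain (slope of the saturation vapor
pressure curve Δ, psychrometric constant γ from elevation, vapor pressures
from the daily temperature extremes, extraterrestrial and clear-sky radiation
from latitude and day of year, net longwave from the Stefan–Boltzmann
formula). Soil heat flux G = 0 at daily time steps; albedo 0.23.

Actual evapotranspiration is ETa = kC · ET0 with a crop coefficient kC
(kC = 1 for a year-round wet peat swamp where moisture never limits
evaporation), and annual runoff closes the balance: RE = P − ETa, assuming no
change in catchment water storage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SiteGeo",
    "WaterBalance",
    "aggregate_daily",
    "wind_to_2m",
    "et0_components",
    "et0_from_terms",
    "et0_penman_monteith",
    "et0_series",
    "annual_et0",
    "eta_from_et0",
    "annual_runoff",
]

#: Solar constant (MJ m⁻² min⁻¹) and Stefan–Boltzmann (MJ K⁻⁴ m⁻² d⁻¹).
GSC = 0.0820
SIGMA_SB = 4.903e-9
ALBEDO = 0.23


@dataclass(frozen=True)
class SiteGeo:
    """Station geography needed by the radiation and wind terms."""

    latitude_deg: float
    elevation_m: float
    anemometer_height_m: float = 2.0

    def __post_init__(self) -> None:
        if not abs(self.latitude_deg) <= 90:
            raise ValueError("latitude must be within ±90°")
        if self.anemometer_height_m <= 0:
            raise ValueError("anemometer height must be positive")


@dataclass(frozen=True)
class WaterBalance:
    """Annual water-balance ledger (all mm yr⁻¹)."""

    p_mm_yr: float
    et0_mm_yr: float
    kc: float
    eta_mm_yr: float
    re_mm_yr: float
    deficit: bool = False  # True when ETa exceeded P


def wind_to_2m(u_z: float, z_m: float) -> float:
    """Adjust wind speed measured at height z to the 2 m standard via the
    FAO-56 logarithmic profile factor 4.87/ln(67.8·z − 5.42)."""
    if z_m == 2.0:
        return u_z
    return u_z * 4.87 / math.log(67.8 * z_m - 5.42)


def aggregate_daily(
    records: pd.DataFrame,
    anemometer_height_m: float = 2.0,
    max_missing_fraction: float = 0.25,
    expected_per_day: int = 96,
) -> pd.DataFrame:
    """Aggregate 15-min meteorology to daily values.

    Per day: rain summed; tmax/tmin/tmean from the interval temperatures; RH
    averaged; solar averaged (W m⁻²) then × 0.0864 → MJ m⁻² d⁻¹; wind
    averaged and height-adjusted to 2 m. Days with more than
    ``max_missing_fraction`` of intervals absent are flagged ``complete=False``.

    ``records`` needs columns timestamp, rain_mm, tair_c, rh_pct,
    solar_w_m2, wind_m_s.
    """
    df = records.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["date"] = df["timestamp"].dt.date
    factor = 4.87 / math.log(67.8 * anemometer_height_m - 5.42) if anemometer_height_m != 2.0 else 1.0
    daily = df.groupby("date").agg(
        rain_mm=("rain_mm", "sum"),
        tmax_c=("tair_c", "max"),
        tmin_c=("tair_c", "min"),
        tmean_c=("tair_c", "mean"),
        rh_mean_pct=("rh_pct", "mean"),
        solar_mean_w_m2=("solar_w_m2", "mean"),
        wind_mean_m_s=("wind_m_s", "mean"),
        n_intervals=("tair_c", "count"),
    ).reset_index()
    daily["rs_mj_m2_d"] = daily["solar_mean_w_m2"] * 0.0864
    daily["u2_m_s"] = daily["wind_mean_m_s"] * factor
    daily["complete"] = daily["n_intervals"] >= expected_per_day * (1 - max_missing_fraction)
    n_bad = int((~daily["complete"]).sum())
    if n_bad:
        logger.warning("%d day(s) flagged incomplete (>%.0f%% intervals missing)",
                       n_bad, 100 * max_missing_fraction)
    return daily.drop(columns=["solar_mean_w_m2", "wind_mean_m_s"])


def _svp(t_c: float) -> float:
    """Saturation vapor pressure (kPa) at air temperature t (°C)."""
    return 0.6108 * math.exp(17.27 * t_c / (t_c + 237.3))


def et0_from_terms(
    delta: float,
    gamma: float,
    tmean_c: float,
    u2_m_s: float,
    es: float,
    ea: float,
    rn: float,
    g: float = 0.0,
) -> float:
    """Combine pre-computed FAO-56 terms into ET0 (mm d⁻¹), floored at 0.

    Zero available energy (Rn − G = 0) with calm air (u2 = 0) gives exactly
    0: both the radiation and aerodynamic terms of the numerator vanish.
    """
    num = 0.408 * delta * (rn - g) + gamma * (900.0 / (tmean_c + 273.0)) * u2_m_s * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2_m_s)
    return max(num / den, 0.0)


def et0_components(
    tmax_c: float,
    tmin_c: float,
    rh_mean_pct: float,
    rs_mj_m2_d: float,
    u2_m_s: float,
    doy: int,
    geo: SiteGeo,
) -> dict[str, float]:
    """Evaluate every FAO-56 intermediate for one day, returned by name.

    Keys: delta, gamma, es, ea, ra, rso, rns, rnl, rn, et0. Rs is clipped to
    the clear-sky Rso inside the longwave cloudiness ratio (with a logged
    warning) as FAO-56 prescribes; ET0 is floored at 0.
    """
    for name, v in (("tmax_c", tmax_c), ("tmin_c", tmin_c), ("rh_mean_pct", rh_mean_pct),
                    ("rs_mj_m2_d", rs_mj_m2_d), ("u2_m_s", u2_m_s)):
        if not math.isfinite(v):
            raise ValueError(f"non-finite input {name}")
    tmean = (tmax_c + tmin_c) / 2.0

    # Slope of the saturation vapor pressure curve at tmean (kPa °C⁻¹)
    delta = 4098.0 * _svp(tmean) / (tmean + 237.3) ** 2

    # Psychrometric constant from barometric pressure at station elevation
    p_kpa = 101.3 * ((293.0 - 0.0065 * geo.elevation_m) / 293.0) ** 5.26
    gamma = 0.000665 * p_kpa

    # Vapor pressures: es from the mean of the saturation values at the
    # daily extremes; ea from mean RH
    es = (_svp(tmax_c) + _svp(tmin_c)) / 2.0
    ea = rh_mean_pct / 100.0 * es

    # Extraterrestrial radiation from latitude and day of year
    phi = math.radians(geo.latitude_deg)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    decl = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    ws = math.acos(min(1.0, max(-1.0, -math.tan(phi) * math.tan(decl))))
    ra = (24.0 * 60.0 / math.pi) * GSC * dr * (
        ws * math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(decl) * math.sin(ws)
    )

    # Clear-sky and net radiation (albedo 0.23; G = 0 daily)
    rso = (0.75 + 2e-5 * geo.elevation_m) * ra
    rns = (1.0 - ALBEDO) * rs_mj_m2_d
    rs_ratio_input = rs_mj_m2_d
    if rso > 0 and rs_mj_m2_d > rso:
        logger.warning("Rs %.2f exceeds clear-sky Rso %.2f; clipped for the longwave ratio",
                       rs_mj_m2_d, rso)
        rs_ratio_input = rso
    ratio = rs_ratio_input / rso if rso > 0 else 1.0
    tmax_k4 = (tmax_c + 273.16) ** 4
    tmin_k4 = (tmin_c + 273.16) ** 4
    rnl = SIGMA_SB * (tmax_k4 + tmin_k4) / 2.0 * (0.34 - 0.14 * math.sqrt(max(ea, 0.0))) * (
        1.35 * ratio - 0.35
    )
    rn = rns - rnl

    et0 = et0_from_terms(delta, gamma, tmean, u2_m_s, es, ea, rn)
    return {
        "delta": delta, "gamma": gamma, "es": es, "ea": ea, "ra": ra,
        "rso": rso, "rns": rns, "rnl": rnl, "rn": rn, "et0": et0,
    }


def et0_penman_monteith(
    tmax_c: float,
    tmin_c: float,
    rh_mean_pct: float,
    rs_mj_m2_d: float,
    u2_m_s: float,
    doy: int,
    geo: SiteGeo,
) -> float:
    """Daily FAO-56 Penman–Monteith reference evapotranspiration (mm d⁻¹)."""
    return et0_components(tmax_c, tmin_c, rh_mean_pct, rs_mj_m2_d, u2_m_s, doy, geo)["et0"]


def et0_series(daily: pd.DataFrame, geo: SiteGeo) -> pd.Series:
    """ET0 for each row of a daily-met table (see :func:`aggregate_daily`);
    incomplete days yield NaN."""
    out = []
    complete = daily["complete"] if "complete" in daily else pd.Series(True, index=daily.index)
    for row, ok in zip(daily.itertuples(index=False), complete):
        if not ok:
            out.append(np.nan)
            continue
        doy = pd.Timestamp(row.date).dayofyear
        out.append(et0_penman_monteith(
            row.tmax_c, row.tmin_c, row.rh_mean_pct, row.rs_mj_m2_d, row.u2_m_s, doy, geo
        ))
    return pd.Series(out, index=daily.index, name="et0_mm_d")


def annual_et0(
    daily_et0: pd.Series | np.ndarray,
    months: pd.Series | None = None,
    max_missing_fraction: float = 0.10,
) -> float:
    """Sum daily ET0 to an annual total (mm yr⁻¹).

    Missing days (NaN) are imputed with the month-of-year mean when a month
    index is supplied and no more than ``max_missing_fraction`` of days are
    missing; more than that fails loudly.
    """
    x = pd.Series(np.asarray(daily_et0, dtype=float))
    n_missing = int(x.isna().sum())
    if n_missing > max_missing_fraction * len(x):
        raise ValueError(f"{n_missing}/{len(x)} daily ET0 values missing (> {max_missing_fraction:.0%})")
    if n_missing:
        if months is None:
            raise ValueError("month index required to impute missing daily ET0")
        m = pd.Series(np.asarray(months)).reset_index(drop=True)
        fill = x.groupby(m).transform("mean")
        x = x.fillna(fill)
        logger.info("imputed %d missing daily ET0 value(s) by month-of-year mean", n_missing)
    return float(x.sum())


def eta_from_et0(et0_mm_yr: float, kc: float = 1.0) -> float:
    """Actual evapotranspiration ETa = kC · ET0."""
    if kc < 0:
        raise ValueError("crop coefficient must be non-negative")
    return kc * et0_mm_yr


def annual_runoff(p_mm_yr: float, eta_mm_yr: float, et0_mm_yr: float | None = None,
                  kc: float = 1.0) -> WaterBalance:
    """Close the annual water balance: RE = P − ETa.

    A negative runoff (water-balance deficit) is permitted but flagged.
    """
    if p_mm_yr < 0 or eta_mm_yr < 0:
        raise ValueError("P and ETa must be non-negative")
    re = p_mm_yr - eta_mm_yr
    deficit = re < 0
    if deficit:
        logger.warning("water-balance deficit: ETa %.0f mm exceeds P %.0f mm", eta_mm_yr, p_mm_yr)
    if et0_mm_yr is None:
        et0_mm_yr = eta_mm_yr / kc if kc > 0 else float("nan")
    return WaterBalance(p_mm_yr, et0_mm_yr, kc, eta_mm_yr, re, deficit)
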