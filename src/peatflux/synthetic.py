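"""Synthetic field campaign with known ground truth.

Emulates the study design the pipeline was built for — 2 peat-swamp-forest
sites × 10 plots × 12 monthly campaigns × 3 consecutive days × 3 chamber
replicates of 120-s runs, a 365-day meteorological year logged at 15-min
intervals, daily groundwater levels, and 12 monthly triplicate DOC/POC river
samplings — so every pipeline stage can be exercised at desk scale and
parameter recovery verified against latent truths.

Flux model: site-fixed mean + Gaussian plot and month random effects +
Gaussian run-level residual, all on the annual mass-flux scale; CH4 fluxes
are truncated at zero. Each run's latent flux is converted to a mole-fraction
slope by inverting the chamber gas-law relation for the configured geometry,
and the concentration series is baseline + slope·t + Gaussian instrument
noise. A configurable fraction of runs instead receives a rapidly saturating
(chamber-feedback-shaped) response whose linear fit fails QC.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chamber import ChamberRun
from .constants import BASELINE_PPM, GASES, R_GAS, mg_ha_yr_to_umol

__all__ = [
    "MetYearConfig",
    "WaterSamplingConfig",
    "ScenarioConfig",
    "generate_chamber_runs",
    "generate_met_year",
    "generate_water_samples",
    "generate_groundwater",
    "scenario_manifest",
]

#: Time constant (s) of the saturating response given to QC-failing runs.
#: Short enough that the post-dead-band record is essentially flat, so the
#: linear fit's R² collapses for both gases.
QC_FAIL_TAU_S = 8.0


@dataclass
class MetYearConfig:
    """Rainfall regime and weather baselines for the synthetic met year.

    Defaults emulate a humid-tropical lowland year: ~2130 mm rain with a
    two-season sinusoidal wet-day regime, 25–30 °C air temperature with a
    diurnal cycle, high humidity, and light winds.
    """

    annual_rain_mm: float = 2130.0
    wet_day_prob: float = 0.45
    wet_season_amp: float = 0.35  # relative seasonal modulation of rain
    wet_season_peak_doy: int = 350  # wettest around mid-December
    temp_mean_c: float = 27.0
    temp_seasonal_amp_c: float = 0.8
    temp_diurnal_amp_c: float = 3.5
    temp_noise_c: float = 0.6
    rh_mean_pct: float = 85.0
    rh_diurnal_amp_pct: float = 8.0
    rh_noise_pct: float = 3.0
    solar_peak_w_m2: float = 820.0
    wind_mean_m_s: float = 1.0
    wind_noise_m_s: float = 0.4


@dataclass
class WaterSamplingConfig:
    """Monthly river-sampling parameters (DOC/POC triplicates).

    Variability is split into a between-month component and a within-month
    (triplicate) component; POC is realized through the gravimetric pair
    (filter dry/combusted masses and filtered volume) so the reader has to
    invert the same arithmetic the laboratory would.
    """

    doc_mean_mg_l: float = 37.10
    doc_month_sd: float = 3.5
    doc_sample_sd: float = 1.5
    poc_mean_mg_l: float = 17.20
    poc_month_sd: float = 8.5
    poc_sample_sd: float = 3.0
    volume_filtered_l: float = 0.5
    filter_tare_g: float = 0.1000
    oc_fraction: float = 0.50
    ph_mean: float = 4.29
    ph_sd: float = 0.3
    water_temp_mean_c: float = 30.2
    water_temp_sd: float = 1.0


@dataclass
class ScenarioConfig:
    """Campaign design, true fluxes, variance components and noise levels.

    True annual fluxes are per-site mass fluxes (MgCO2 resp. MgCH4 ha⁻¹
    yr⁻¹); variance components are Gaussian on the same scale, keyed by gas.
    ``qc_fail_fraction`` of runs are generated with the saturating response.
    """

    site_ids: tuple[str, ...] = ("PPSF", "SPSF")
    n_plots: int = 10
    n_months: int = 12
    days_per_month: int = 3
    replicates_per_day: int = 3
    true_annual_co2: dict = field(default_factory=lambda: {"PPSF": 12.61, "SPSF": 9.43})
    true_annual_ch4: dict = field(default_factory=lambda: {"PPSF": 0.0259, "SPSF": 0.0170})
    plot_sd: dict = field(default_factory=lambda: {"CO2": 0.3, "CH4": 0.0003})
    month_sd: dict = field(default_factory=lambda: {"CO2": 0.3, "CH4": 0.0003})
    residual_sd: dict = field(default_factory=lambda: {"CO2": 13.4, "CH4": 0.008})
    qc_fail_fraction: float = 0.0
    chamber_volume_m3: float = 0.0058
    collar_area_m2: float = 0.0318
    run_duration_s: float = 120.0
    sample_interval_s: float = 1.0
    baseline_ppm: dict = field(default_factory=lambda: dict(BASELINE_PPM))
    conc_noise_ppm: dict = field(default_factory=lambda: {"CO2": 0.05, "CH4": 0.001})
    air_temp_c_mean: float = 28.0
    air_temp_c_sd: float = 1.5
    pressure_kpa: float = 101.325
    start_date: dt.date = dt.date(2022, 10, 1)
    gw_mean_cm: dict = field(default_factory=lambda: {"PPSF": 19.0, "SPSF": 37.3})
    gw_seasonal_amp_cm: float = 15.0
    gw_noise_cm: float = 3.0
    met_year: MetYearConfig = field(default_factory=MetYearConfig)
    water_sampling: WaterSamplingConfig = field(default_factory=WaterSamplingConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_plots, self.n_months, self.days_per_month, self.replicates_per_day)
        if any(c < 1 for c in counts):
            raise ValueError("all campaign counts must be >= 1")
        sds = [*self.plot_sd.values(), *self.month_sd.values(), *self.residual_sd.values()]
        if any(s < 0 for s in sds):
            raise ValueError("variance components must be non-negative")
        if not 0.0 <= self.qc_fail_fraction <= 1.0:
            raise ValueError("qc_fail_fraction must lie in [0, 1]")
        for site in self.site_ids:
            if site not in self.true_annual_co2 or site not in self.true_annual_ch4:
                raise ValueError(f"no true fluxes configured for site {site!r}")
        if self.chamber_volume_m3 <= 0 or self.collar_area_m2 <= 0:
            raise ValueError("chamber geometry must be positive")
        numeric = [
            *self.true_annual_co2.values(), *self.true_annual_ch4.values(), *sds,
            self.qc_fail_fraction, self.chamber_volume_m3, self.collar_area_m2,
            self.run_duration_s, self.sample_interval_s, self.pressure_kpa,
        ]
        if not all(math.isfinite(v) for v in numeric):
            raise ValueError("configuration values must be finite")

    def true_flux(self, site: str, gas: str) -> float:
        """Configured true annual mass flux (Mg gas ha⁻¹ yr⁻¹)."""
        return (self.true_annual_co2 if gas == "CO2" else self.true_annual_ch4)[site]


def _streams(config: ScenarioConfig) -> dict[str, np.random.Generator]:
    """Independent, reproducible RNG streams per generator."""
    root = np.random.SeedSequence(config.seed)
    names = ("chamber", "met", "water", "groundwater")
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


def _month_date(start: dt.date, month_index: int, day_offset: int) -> dt.date:
    ts = pd.Timestamp(start) + pd.DateOffset(months=month_index, days=9 + day_offset)
    return ts.date()


def generate_chamber_runs(config: ScenarioConfig) -> list[ChamberRun]:
    """Generate the full campaign of chamber runs with latent true fluxes.

    Per run and gas, the latent flux is
    site mean + plot effect + month effect + residual (CH4 truncated at 0),
    the mole-fraction slope is flux · R·T·A / (P·V), and the series is
    baseline + slope·t + noise — or the saturating QC-fail shape for the
    designated fraction of runs.
    """
    rng = _streams(config)["chamber"]
    n_steps = int(round(config.run_duration_s / config.sample_interval_s))
    t = np.arange(n_steps + 1) * config.sample_interval_s
    runs: list[ChamberRun] = []
    for site in config.site_ids:
        plot_eff = {
            gas: rng.normal(0.0, config.plot_sd[gas], config.n_plots) for gas in GASES
        }
        month_eff = {
            gas: rng.normal(0.0, config.month_sd[gas], config.n_months) for gas in GASES
        }
        for m in range(config.n_months):
            for d in range(config.days_per_month):
                date = _month_date(config.start_date, m, d)
                for p in range(config.n_plots):
                    for rep in range(1, config.replicates_per_day + 1):
                        air_t_k = 273.15 + config.air_temp_c_mean + (
                            rng.normal(0.0, config.air_temp_c_sd) if config.air_temp_c_sd else 0.0
                        )
                        mol_air = config.pressure_kpa * 1000.0 * config.chamber_volume_m3 / (
                            R_GAS * air_t_k
                        )
                        qc_fail = bool(rng.random() < config.qc_fail_fraction)
                        series: dict[str, np.ndarray] = {}
                        truth: dict[str, float] = {}
                        for gas in GASES:
                            flux_mg = (
                                config.true_flux(site, gas)
                                + plot_eff[gas][p]
                                + month_eff[gas][m]
                                + (rng.normal(0.0, config.residual_sd[gas])
                                   if config.residual_sd[gas] else 0.0)
                            )
                            if gas == "CH4":
                                flux_mg = max(flux_mg, 0.0)
                            flux_umol = flux_mg * mg_ha_yr_to_umol(gas)
                            truth[gas] = flux_umol
                            slope = flux_umol * config.collar_area_m2 / mol_air
                            if qc_fail:
                                trend = slope * QC_FAIL_TAU_S * (1.0 - np.exp(-t / QC_FAIL_TAU_S))
                            else:
                                trend = slope * t
                            noise_sd = config.conc_noise_ppm[gas]
                            noise = rng.normal(0.0, noise_sd, t.size) if noise_sd else 0.0
                            series[gas] = config.baseline_ppm[gas] + trend + noise
                        runs.append(ChamberRun(
                            run_id=f"{site}-P{p + 1:02d}-M{m + 1:02d}-D{d + 1}-R{rep}",
                            site=site, plot=p + 1, date=date, replicate=rep,
                            elapsed_s=t.copy(), co2_ppm=series["CO2"], ch4_ppm=series["CH4"],
                            air_temp_k=air_t_k, pressure_kpa=config.pressure_kpa,
                            chamber_volume_m3=config.chamber_volume_m3,
                            collar_area_m2=config.collar_area_m2,
                            true_flux_umol=truth, synthetic_qc_fail=qc_fail,
                        ))
    return runs


def generate_met_year(config: ScenarioConfig) -> pd.DataFrame:
    """365 days × 96 15-min weather records; rainfall rescaled so the annual
    total matches the configured amount exactly."""
    mc = config.met_year
    rng = _streams(config)["met"]
    n_days = 365
    start = pd.Timestamp(config.start_date)
    timestamps = pd.date_range(start, periods=n_days * 96, freq="15min")
    doy = np.array([ts.dayofyear for ts in timestamps[::96]])

    # Daily rainfall: seasonally modulated wet-day process, gamma amounts,
    # then exact rescaling to the configured annual depth.
    season = 1.0 + mc.wet_season_amp * np.cos(
        2.0 * np.pi * (doy - mc.wet_season_peak_doy) / 365.0
    )
    wet = rng.random(n_days) < np.clip(mc.wet_day_prob * season, 0.0, 1.0)
    amounts = rng.gamma(shape=1.2, scale=10.0, size=n_days) * season * wet
    if mc.annual_rain_mm > 0:
        if amounts.sum() == 0.0:
            amounts = np.ones(n_days)
        amounts *= mc.annual_rain_mm / amounts.sum()
    else:
        amounts[:] = 0.0

    rain = np.zeros(n_days * 96)
    for i, amt in enumerate(amounts):
        if amt <= 0:
            continue
        n_int = int(rng.integers(2, 13))  # rain event spread over 0.5–3 h
        start_idx = int(rng.integers(0, 96 - n_int))
        rain[i * 96 + start_idx: i * 96 + start_idx + n_int] += amt / n_int

    hour = timestamps.hour.to_numpy() + timestamps.minute.to_numpy() / 60.0
    doy_full = np.repeat(doy, 96)
    seasonal_t = mc.temp_seasonal_amp_c * np.cos(2.0 * np.pi * (doy_full - 60) / 365.0)
    diurnal = np.cos(2.0 * np.pi * (hour - 14.0) / 24.0)
    tair = (
        mc.temp_mean_c + seasonal_t + mc.temp_diurnal_amp_c * diurnal
        + (rng.normal(0.0, mc.temp_noise_c, rain.size) if mc.temp_noise_c else 0.0)
    )
    rh = np.clip(
        mc.rh_mean_pct - mc.rh_diurnal_amp_pct * diurnal
        + (rng.normal(0.0, mc.rh_noise_pct, rain.size) if mc.rh_noise_pct else 0.0),
        0.0, 100.0,
    )
    # Daylight half-sine, damped on wet days (cloud cover)
    daylight = np.clip(np.sin(np.pi * (hour - 6.0) / 12.0), 0.0, None)
    cloud = np.repeat(np.where(wet, 0.55, 0.85), 96)
    solar = np.clip(mc.solar_peak_w_m2 * daylight * cloud, 0.0, None)
    wind = np.abs(
        mc.wind_mean_m_s
        + (rng.normal(0.0, mc.wind_noise_m_s, rain.size) if mc.wind_noise_m_s else 0.0)
    )
    return pd.DataFrame({
        "timestamp": timestamps, "rain_mm": rain, "tair_c": tair,
        "rh_pct": rh, "solar_w_m2": solar, "wind_m_s": wind,
    })


def generate_water_samples(config: ScenarioConfig) -> pd.DataFrame:
    """12 monthly sampling events × (3 DOC + 3 POC) river samples.

    POC samples carry the gravimetric triple (dry mass, combusted mass,
    filtered volume) consistent with the latent POC concentration and the
    configured organic-carbon fraction.
    """
    wc = config.water_sampling
    rng = _streams(config)["water"]
    rows = []
    for m in range(config.n_months):
        date = _month_date(config.start_date, m, 5)
        doc_m = wc.doc_mean_mg_l + (rng.normal(0.0, wc.doc_month_sd) if wc.doc_month_sd else 0.0)
        poc_m = wc.poc_mean_mg_l + (rng.normal(0.0, wc.poc_month_sd) if wc.poc_month_sd else 0.0)
        ph = wc.ph_mean + (rng.normal(0.0, wc.ph_sd) if wc.ph_sd else 0.0)
        wtemp = wc.water_temp_mean_c + (
            rng.normal(0.0, wc.water_temp_sd) if wc.water_temp_sd else 0.0
        )
        for _ in range(3):
            doc = max(
                doc_m + (rng.normal(0.0, wc.doc_sample_sd) if wc.doc_sample_sd else 0.0), 0.0
            )
            rows.append({
                "date": date, "analyte": "DOC", "doc_mg_l": doc,
                "filter_dry_g": np.nan, "filter_combusted_g": np.nan,
                "volume_filtered_l": np.nan, "water_ph": ph, "water_temp_c": wtemp,
            })
        for _ in range(3):
            poc = max(
                poc_m + (rng.normal(0.0, wc.poc_sample_sd) if wc.poc_sample_sd else 0.0), 0.0
            )
            pom_g = poc / wc.oc_fraction * wc.volume_filtered_l / 1000.0
            rows.append({
                "date": date, "analyte": "POC", "doc_mg_l": np.nan,
                "filter_dry_g": wc.filter_tare_g + pom_g,
                "filter_combusted_g": wc.filter_tare_g,
                "volume_filtered_l": wc.volume_filtered_l,
                "water_ph": ph, "water_temp_c": wtemp,
            })
    return pd.DataFrame(rows)


def generate_groundwater(config: ScenarioConfig) -> pd.DataFrame:
    """Daily groundwater level (cm above the peat surface) per site.

    Plumbing covariate only — no coupling to the generated fluxes."""
    rng = _streams(config)["groundwater"]
    dates = pd.date_range(pd.Timestamp(config.start_date), periods=365, freq="D")
    doy = dates.dayofyear.to_numpy()
    rows = []
    for site in config.site_ids:
        seasonal = config.gw_seasonal_amp_cm * np.cos(
            2.0 * np.pi * (doy - config.met_year.wet_season_peak_doy) / 365.0
        )
        noise = rng.normal(0.0, config.gw_noise_cm, doy.size) if config.gw_noise_cm else 0.0
        level = config.gw_mean_cm.get(site, 20.0) + seasonal + noise
        rows.append(pd.DataFrame({"date": dates.date, "site": site, "gwl_cm": level}))
    return pd.concat(rows, ignore_index=True)


def scenario_manifest(config: ScenarioConfig) -> dict:
    """Scenario configuration plus latent truths, for the run manifest."""
    cfg = dataclasses.asdict(config)
    cfg["start_date"] = config.start_date.isoformat()
    truths = {
        site: {
            gas: {
                "mass_mg_ha_yr": config.true_flux(site, gas),
                "molar_umol_m2_s": config.true_flux(site, gas) * mg_ha_yr_to_umol(gas),
            }
            for gas in GASES
        }
        for site in config.site_ids
    }
    return {"config": cfg, "true_fluxes": truths}
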