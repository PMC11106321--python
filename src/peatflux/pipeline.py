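"""Stage orchestration, configuration, and the reproduction report.

Three modes:

* ``synthetic`` — generate a campaign with :mod:`peatflux.synthetic`, write
  the raw CSVs, then run every stage on them.
* ``files`` — run the stages on user-supplied CSVs.
* ``summary`` — inject site-level annual summary values (the bundled
  Muara Siran campaign file by default) directly into the budget chain,
  bypassing raw fitting; this reproduces the campaign's headline accounting
  in seconds.

Every stage writes its own artifact next to the final report so each report
number is recomputable from shipped outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from . import budget as bd
from . import chamber as ch
from . import evapotranspiration as et
from . import fluvial as fl
from . import io as pio
from . import synthetic as syn
from .constants import GWP100_CH4, R2_THRESHOLDS

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "load_campaign_summary", "summary_report", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration (see the bundled example TOML in the docs)."""

    mode: str = "synthetic"  # synthetic | files | summary
    outdir: Path = Path("peatflux_out")
    seed: int = 0
    # files mode inputs
    chamber_series_csv: Path | None = None
    chamber_meta_csv: Path | None = None
    met_csv: Path | None = None
    water_csv: Path | None = None
    # station geography (study-region defaults: equatorial lowland)
    latitude_deg: float = -0.03
    elevation_m: float = 10.0
    anemometer_height_m: float = 2.0
    # processing options
    deadband_s: float = 10.0
    stop_s: float = 120.0
    co2_r2_threshold: float = R2_THRESHOLDS["CO2"]
    ch4_r2_threshold: float = R2_THRESHOLDS["CH4"]
    outlier_k: float = 3.0
    kc: float = 1.0
    gwp100: float = GWP100_CH4
    se_rule: str = "quadrature"
    params_file: Path | None = None  # partitioning ratios / carbon inputs
    scenario: syn.ScenarioConfig = field(default_factory=syn.ScenarioConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files", "summary"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("co2_r2_threshold", "ch4_r2_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.mode == "files":
            for name in ("chamber_series_csv", "chamber_meta_csv", "met_csv", "water_csv"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name}: missing input file {p}")

    @property
    def thresholds(self) -> dict[str, float]:
        return {"CO2": self.co2_r2_threshold, "CH4": self.ch4_r2_threshold}

    @property
    def geo(self) -> et.SiteGeo:
        return et.SiteGeo(self.latitude_deg, self.elevation_m, self.anemometer_height_m)


def load_config(path: Path) -> RunConfig:
    """Read a flat TOML run configuration."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    scenario_raw = raw.pop("scenario", {})
    scenario = syn.ScenarioConfig(**scenario_raw) if scenario_raw else syn.ScenarioConfig()
    for key in ("outdir", "chamber_series_csv", "chamber_meta_csv", "met_csv", "water_csv",
                "params_file"):
        if key in raw and raw[key] is not None:
            raw[key] = Path(raw[key])
    cfg = RunConfig(scenario=scenario, **raw)
    if "seed" in raw:
        cfg.scenario.seed = cfg.seed
    return cfg


def load_campaign_summary(path: Path | None = None) -> dict:
    """Load the site-summary parameter file (bundled Muara Siran campaign
    values unless a path is given)."""
    if path is not None:
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with resources.files("peatflux.data").joinpath("muara_siran.toml").open("rb") as fh:
        return tomllib.load(fh)


def summary_report(params: dict, se_rule: str | None = None) -> dict:
    """Run the budget chain on site-level summary inputs.

    Builds annual-flux objects from the given site means ± SEs, closes the
    water balance, computes the fluvial export from the annual mean TOC and
    runoff, then derives site totals, partitioned budgets, and the landscape
    carbon-loss total.
    """
    opts = params.get("options", {})
    gwp = float(opts.get("gwp100", GWP100_CH4))
    se_rule = se_rule or opts.get("se_rule", "quadrature")

    wbp = params["water_balance"]
    wb = et.annual_runoff(
        float(wbp["p_mm_yr"]), float(wbp["eta_mm_yr"]), kc=float(wbp.get("kc", 1.0))
    )
    wq = params["water_quality"]
    export = fl.toc_export(float(wq["toc_mg_l"]), wb.re_mm_yr, float(wq.get("toc_se", 0.0)))
    doc_pct = fl.doc_share(float(wq["doc_mg_l"]), float(wq["toc_mg_l"]))

    sites: dict[str, dict] = {}
    co2_fluxes, ch4_fluxes = [], []
    for site, sp in params["sites"].items():
        n = int(sp.get("n", 2))
        co2 = ch.AnnualFlux(site, "CO2", float(sp["co2_mgco2_ha_yr"]), float(sp["co2_se"]),
                            n, "MgCO2 ha-1 yr-1")
        ch4e = ch.AnnualFlux(site, "CH4", float(sp["ch4_co2e_ha_yr"]), float(sp["ch4_co2e_se"]),
                             n, "MgCO2e ha-1 yr-1")
        total = ch.site_total_co2e(co2, ch4e)
        result = bd.site_budget(
            co2, ch4e, export,
            bd.PartitionSpec(site, float(sp["rh_ratio"])),
            bd.CarbonInputs(
                float(sp["litterfall_mgc"]), float(sp["litterfall_se"]),
                float(sp["root_mortality_mgc"]), float(sp["root_mortality_se"]),
            ),
        )
        co2_fluxes.append(co2)
        ch4_fluxes.append(ch4e)
        sites[site] = {
            "co2": dataclasses.asdict(co2),
            "ch4_co2e": dataclasses.asdict(ch4e),
            "total_co2e": dataclasses.asdict(total),
            "ch4_mass_mgch4": ch4e.mean / gwp,
            "budget": dataclasses.asdict(result),
        }

    land_co2 = ch.landscape_mean(co2_fluxes, se_rule)
    land_ch4 = ch.landscape_mean(ch4_fluxes, se_rule)
    loss = bd.total_carbon_loss(land_co2, land_ch4, export)
    return {
        "water_balance": dataclasses.asdict(wb),
        "fluvial": {**dataclasses.asdict(export), "doc_share_pct": doc_pct},
        "sites": sites,
        "landscape": {
            "co2": dataclasses.asdict(land_co2),
            "ch4_co2e": dataclasses.asdict(land_ch4),
            "total_loss": dataclasses.asdict(loss),
        },
    }


def _flux_stage(cfg: RunConfig, runs, outdir: Path) -> dict[tuple[str, str], ch.AnnualFlux]:
    annual, records, daily = ch.compute_annual_fluxes(
        runs, cfg.deadband_s, cfg.stop_s, cfg.thresholds, cfg.outlier_k
    )
    pio.flux_records_frame(records).to_csv(outdir / "flux_records.csv", index=False)
    daily.to_csv(outdir / "daily_plot_fluxes.csv", index=False)
    pio.annual_summary_frame(annual).to_csv(outdir / "annual_fluxes.csv", index=False)
    n_rej = sum(1 for r in records if not r.qc_pass)
    n_out = sum(1 for r in records if r.outlier)
    logger.info("flux stage: %d records, %d QC-rejected, %d outliers", len(records), n_rej, n_out)
    return annual


def _water_stage(cfg: RunConfig, met: pd.DataFrame, outdir: Path) -> et.WaterBalance:
    daily = et.aggregate_daily(met, cfg.anemometer_height_m)
    et0 = et.et0_series(daily, cfg.geo)
    daily = daily.assign(et0_mm_d=et0)
    daily.to_csv(outdir / "daily_met.csv", index=False)
    months = pd.to_datetime(daily["date"]).dt.month
    et0_yr = et.annual_et0(et0, months)
    eta = et.eta_from_et0(et0_yr, cfg.kc)
    wb = et.annual_runoff(float(daily["rain_mm"].sum()), eta, et0_yr, cfg.kc)
    pio.write_json(dataclasses.asdict(wb), outdir / "water_balance.json")
    return wb


def _fluvial_stage(samples: pd.DataFrame, wb: et.WaterBalance, outdir: Path) -> tuple[fl.FluvialExport, float]:
    monthly = fl.monthly_concentrations(samples)
    monthly.to_csv(outdir / "monthly_concentrations.csv", index=False)
    cw, cw_se = fl.annual_mean_toc(monthly)
    export = fl.toc_export(cw, wb.re_mm_yr, cw_se)
    valid = monthly[monthly["valid"]]
    doc_pct = fl.doc_share(float(valid["doc_mean"].mean()), cw)
    pio.write_json({**dataclasses.asdict(export), "doc_share_pct": doc_pct},
                   outdir / "fluvial_export.json")
    return export, doc_pct


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the report dict (also written as ``report.json``; a
    human-readable ``report.txt`` mirrors the summary tables).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.mode == "summary":
        report = summary_report(load_campaign_summary(config.params_file), config.se_rule)
        pio.write_json(report, outdir / "report.json")
        (outdir / "report.txt").write_text(format_report(report))
        return report

    if config.mode == "synthetic":
        config.scenario.seed = config.seed
        runs = syn.generate_chamber_runs(config.scenario)
        met = syn.generate_met_year(config.scenario)
        samples = syn.generate_water_samples(config.scenario)
        pio.write_chamber_csvs(runs, outdir / "chamber_series.csv", outdir / "chamber_meta.csv")
        pio.write_met_csv(met, outdir / "met_15min.csv")
        pio.write_water_csv(samples, outdir / "water_samples.csv")
        pio.write_json(syn.scenario_manifest(config.scenario), outdir / "scenario_manifest.json")
    else:  # files
        runs = pio.read_chamber_runs(config.chamber_series_csv, config.chamber_meta_csv)
        met = pio.read_met_csv(config.met_csv)
        samples = pio.read_water_csv(config.water_csv)

    annual = _flux_stage(config, runs, outdir)
    wb = _water_stage(config, met, outdir)
    export, doc_pct = _fluvial_stage(samples, wb, outdir)

    params = load_campaign_summary(config.params_file)
    sites_out: dict[str, dict] = {}
    co2_fluxes, ch4e_fluxes = [], []
    for site in sorted({s for s, _ in annual}):
        if (site, "CO2") not in annual or (site, "CH4") not in annual:
            logger.warning("site %s missing a gas; skipped in budgets", site)
            continue
        co2 = annual[(site, "CO2")]
        ch4e = ch.ch4_to_co2e(annual[(site, "CH4")], config.gwp100)
        total = ch.site_total_co2e(co2, ch4e)
        entry: dict = {
            "co2": dataclasses.asdict(co2),
            "ch4_co2e": dataclasses.asdict(ch4e),
            "total_co2e": dataclasses.asdict(total),
        }
        sp = params["sites"].get(site)
        if sp is not None:
            result = bd.site_budget(
                co2, ch4e, export,
                bd.PartitionSpec(site, float(sp["rh_ratio"])),
                bd.CarbonInputs(
                    float(sp["litterfall_mgc"]), float(sp["litterfall_se"]),
                    float(sp["root_mortality_mgc"]), float(sp["root_mortality_se"]),
                ),
            )
            entry["budget"] = dataclasses.asdict(result)
        else:
            logger.warning("no partitioning parameters for site %s; budget skipped", site)
        co2_fluxes.append(co2)
        ch4e_fluxes.append(ch4e)
        sites_out[site] = entry

    report: dict = {
        "water_balance": dataclasses.asdict(wb),
        "fluvial": {**dataclasses.asdict(export), "doc_share_pct": doc_pct},
        "sites": sites_out,
    }
    if len(co2_fluxes) >= 2:
        land_co2 = ch.landscape_mean(co2_fluxes, config.se_rule)
        land_ch4 = ch.landscape_mean(ch4e_fluxes, config.se_rule)
        loss = bd.total_carbon_loss(land_co2, land_ch4, export)
        report["landscape"] = {
            "co2": dataclasses.asdict(land_co2),
            "ch4_co2e": dataclasses.asdict(land_ch4),
            "total_loss": dataclasses.asdict(loss),
        }
    pio.write_json(report, outdir / "report.json")
    (outdir / "report.txt").write_text(format_report(report))
    return report


def format_report(report: dict) -> str:
    """Human-readable summary mirroring the campaign's reporting tables."""
    lines = []
    wb = report["water_balance"]
    lines.append("Annual water balance (mm yr-1)")
    lines.append(f"  P = {wb['p_mm_yr']:.0f}   ET0 = {wb['et0_mm_yr']:.0f}   "
                 f"kC = {wb['kc']:.2f}   ETa = {wb['eta_mm_yr']:.0f}   RE = {wb['re_mm_yr']:.0f}")
    fv = report["fluvial"]
    lines.append("Fluvial organic-carbon export")
    lines.append(f"  C_W = {fv['cw_mg_l']:.2f} ± {fv['cw_se']:.2f} mg L-1   "
                 f"J = {fv['j_gc_m2_yr']:.2f} g C m-2 yr-1   "
                 f"= {fv['j_mgco2e_ha_yr']:.2f} ± {fv['j_co2e_se']:.2f} MgCO2e ha-1 yr-1   "
                 f"DOC share = {fv['doc_share_pct']:.0f}%")
    lines.append("Annual site fluxes")
    for site, s in report["sites"].items():
        lines.append(
            f"  {site}: CO2 {s['co2']['mean']:.2f} ± {s['co2']['se']:.2f} MgCO2, "
            f"CH4 {s['ch4_co2e']['mean']:.2f} ± {s['ch4_co2e']['se']:.2f} MgCO2e, "
            f"total {s['total_co2e']['mean']:.2f} ± {s['total_co2e']['se']:.2f} MgCO2e ha-1 yr-1"
        )
        if "budget" in s:
            b = s["budget"]
            lines.append(
                f"    soil resp {b['total_soil_resp_mgc']:.1f} ± {b['total_soil_resp_se']:.1f} MgC, "
                f"Rh {b['rh_mgc']:.1f} ± {b['rh_se']:.1f} MgC, "
                f"onsite {b['onsite_mgco2e']:.1f} ± {b['onsite_mgco2e_se']:.1f} MgCO2e, "
                f"peat budget {b['peat_budget_co2e']:.1f} ± {b['peat_budget_co2e_se']:.1f} MgCO2e"
            )
    if "landscape" in report:
        ld = report["landscape"]
        tl = ld["total_loss"]
        lines.append("Landscape means")
        lines.append(
            f"  CO2 {ld['co2']['mean']:.2f} ± {ld['co2']['se']:.2f} MgCO2, "
            f"CH4 {ld['ch4_co2e']['mean']:.2f} ± {ld['ch4_co2e']['se']:.2f} MgCO2e, "
            f"total loss {tl['total_loss']:.2f} ± {tl['total_se']:.2f} MgCO2e ha-1 yr-1 "
            f"(fluvial share {tl['fluvial_fraction']:.1f}%)"
        )
    return "\n".join(lines) + "\n"
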