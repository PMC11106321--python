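"""Fluvial organic-carbon export from monthly river water samples.

Monthly triplicate DOC and POC concentrations are averaged to monthly TOC
(TOC = DOC + POC), the annual mean TOC concentration C_W is the unweighted
mean of the monthly values, and the annual export is

    J (g C m⁻² yr⁻¹) = C_W (g C m⁻³) × R_E (m yr⁻¹)

where mg L⁻¹ ≡ g m⁻³ for fresh water and R_E is the water-balance runoff.
POC is measured gravimetrically: particulate organic matter is the filter
mass lost between oven-drying and combustion divided by the volume filtered,
converted to carbon with a 50% organic-carbon content.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import C_TO_CO2

logger = logging.getLogger(__name__)

__all__ = [
    "FluvialExport",
    "poc_concentration",
    "monthly_concentrations",
    "annual_mean_toc",
    "toc_export",
    "doc_share",
]

#: Organic-carbon fraction of particulate organic matter.
DEFAULT_OC_FRACTION = 0.50

#: g C m⁻² yr⁻¹ → Mg ha⁻¹ yr⁻¹.
G_M2_TO_MG_HA = 0.01


@dataclass(frozen=True)
class FluvialExport:
    """Annual fluvial organic-carbon export with its uncertainty."""

    cw_mg_l: float
    cw_se: float
    re_mm_yr: float
    j_gc_m2_yr: float
    j_se: float
    j_mgco2e_ha_yr: float
    j_co2e_se: float


def poc_concentration(
    dry_g: float,
    combusted_g: float,
    volume_l: float,
    oc_fraction: float = DEFAULT_OC_FRACTION,
) -> float:
    """POC (mg C L⁻¹) from filter gravimetry.

    POM mg L⁻¹ = (dry − combusted)·1000/volume; POC = POM × oc_fraction.
    A negative mass difference (weighing noise) is clamped to 0 with a
    logged flag rather than raised.
    """
    if volume_l <= 0:
        raise ValueError("filtered volume must be positive")
    diff_g = dry_g - combusted_g
    if diff_g < 0:
        logger.warning("combusted mass exceeds dry mass by %.4g g; POC clamped to 0", -diff_g)
        return 0.0
    return diff_g * 1000.0 / volume_l * oc_fraction


def monthly_concentrations(
    samples: pd.DataFrame, oc_fraction: float = DEFAULT_OC_FRACTION
) -> pd.DataFrame:
    """Triplicate means and SEs of DOC and POC per calendar month.

    ``samples`` columns: date, analyte (DOC|POC), doc_mg_l, filter_dry_g,
    filter_combusted_g, volume_filtered_l. Months missing either analyte are
    flagged invalid and excluded from the annual mean with a warning.
    """
    df = samples.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["month"] = df["date"].dt.to_period("M")
    rows = []
    for month, grp in df.groupby("month"):
        doc = grp.loc[grp["analyte"] == "DOC", "doc_mg_l"].astype(float).to_numpy()
        poc_grp = grp[grp["analyte"] == "POC"]
        poc = np.array([
            poc_concentration(r.filter_dry_g, r.filter_combusted_g, r.volume_filtered_l, oc_fraction)
            for r in poc_grp.itertuples(index=False)
        ])
        valid = doc.size >= 1 and poc.size >= 1
        if not valid:
            logger.warning("month %s missing an analyte; excluded from the annual mean", month)
        rows.append({
            "month": str(month),
            "doc_mean": doc.mean() if doc.size else np.nan,
            "doc_se": doc.std(ddof=1) / math.sqrt(doc.size) if doc.size > 1 else 0.0,
            "poc_mean": poc.mean() if poc.size else np.nan,
            "poc_se": poc.std(ddof=1) / math.sqrt(poc.size) if poc.size > 1 else 0.0,
            "n_doc": doc.size,
            "n_poc": poc.size,
            "valid": valid,
        })
    out = pd.DataFrame(rows)
    out["toc_mean"] = out["doc_mean"] + out["poc_mean"]
    return out


def annual_mean_toc(monthly: pd.DataFrame) -> tuple[float, float]:
    """Annual mean TOC concentration C_W ± SE across the valid months."""
    valid = monthly[monthly["valid"]] if "valid" in monthly else monthly
    if len(valid) < 1:
        raise ValueError("no valid months")
    toc = valid["toc_mean"].to_numpy(dtype=float)
    cw = float(toc.mean())
    se = float(toc.std(ddof=1)) / math.sqrt(len(toc)) if len(toc) > 1 else 0.0
    return cw, se


def toc_export(
    cw_mg_l: float,
    re_mm_yr: float,
    cw_se: float = 0.0,
) -> FluvialExport:
    """Annual fluvial export J = C_W × R_E, in g C m⁻² yr⁻¹ and MgCO2e ha⁻¹ yr⁻¹.

    C_W in mg L⁻¹ is numerically g C m⁻³; R_E enters in m yr⁻¹ (mm/1000).
    The CO2e conversion is J × 0.01 (g m⁻² → Mg ha⁻¹) × 44/12. Runoff is
    treated as fixed, so the SE scales with the C_W SE only. A negative
    runoff (deficit year) yields zero export with a warning.
    """
    if cw_mg_l < 0:
        raise ValueError("TOC concentration must be non-negative")
    if re_mm_yr < 0:
        logger.warning("negative runoff %.0f mm (water-balance deficit); export set to 0", re_mm_yr)
        return FluvialExport(cw_mg_l, cw_se, re_mm_yr, 0.0, 0.0, 0.0, 0.0)
    re_m = re_mm_yr / 1000.0
    j = cw_mg_l * re_m
    j_se = cw_se * re_m
    co2e = j * G_M2_TO_MG_HA * C_TO_CO2
    co2e_se = j_se * G_M2_TO_MG_HA * C_TO_CO2
    return FluvialExport(cw_mg_l, cw_se, re_mm_yr, j, j_se, co2e, co2e_se)


def doc_share(doc_mean: float, toc_mean: float) -> float:
    """Percent of TOC that is dissolved (report tables round to integer %)."""
    if toc_mean <= 0:
        raise ValueError("TOC must be positive")
    return 100.0 * doc_mean / toc_mean
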