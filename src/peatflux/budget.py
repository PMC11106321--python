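"""Peat carbon budgets: respiration partitioning, onsite CO2 budget, and the
site and landscape carbon-loss totals.

Sign convention: a budget is carbon *output minus input*, so negative values
are a net removal (peat accumulation). The onsite CO2 budget is heterotrophic
soil respiration minus carbon inputs from litterfall and root mortality; the
peat carbon budget adds the CH4 and fluvial loss terms. All uncertainties
combine in quadrature for linear combinations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .chamber import AnnualFlux
from .constants import C_TO_CO2, CO2_TO_C
from .fluvial import FluvialExport

__all__ = [
    "PartitionSpec",
    "CarbonInputs",
    "BudgetResult",
    "LandscapeTotal",
    "propagate_se",
    "co2_mass_to_carbon",
    "carbon_to_co2e",
    "heterotrophic_respiration",
    "onsite_co2_budget",
    "peat_carbon_budget",
    "total_carbon_loss",
    "site_budget",
]


@dataclass(frozen=True)
class PartitionSpec:
    """Fraction of total soil respiration that is heterotrophic at one site."""

    site: str
    rh_ratio: float
    rh_ratio_se: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rh_ratio <= 1.0:
            raise ValueError("rh_ratio must lie in [0, 1]")


@dataclass(frozen=True)
class CarbonInputs:
    """Annual carbon inputs to the peat (MgC ha⁻¹ yr⁻¹, literature values)."""

    litterfall: float
    litterfall_se: float
    root_mortality: float
    root_mortality_se: float

    def __post_init__(self) -> None:
        if min(self.litterfall, self.root_mortality) < 0:
            raise ValueError("carbon inputs must be non-negative")
        if min(self.litterfall_se, self.root_mortality_se) < 0:
            raise ValueError("SEs must be non-negative")


@dataclass(frozen=True)
class BudgetResult:
    """Per-site budget ledger. Negative = net removal."""

    site: str
    total_soil_resp_mgc: float
    total_soil_resp_se: float
    rh_mgc: float
    rh_se: float
    onsite_mgc: float
    onsite_mgc_se: float
    onsite_mgco2e: float
    onsite_mgco2e_se: float
    ch4_co2e: float
    ch4_co2e_se: float
    fluvial_co2e: float
    fluvial_co2e_se: float
    peat_budget_co2e: float
    peat_budget_co2e_se: float


@dataclass(frozen=True)
class LandscapeTotal:
    """Landscape-mean annual carbon loss and its composition."""

    co2_mean: float
    co2_se: float
    ch4_mean: float
    ch4_se: float
    fluvial: float
    fluvial_se: float
    total_loss: float
    total_se: float
    fluvial_fraction: float  # percent of the total loss


def propagate_se(terms: Sequence[tuple[float, float]]) -> float:
    """Quadrature SE of a linear combination: √Σ(scaleᵢ·seᵢ)²."""
    for se, _ in terms:
        if se < 0:
            raise ValueError("SEs must be non-negative")
    return math.sqrt(sum((se * scale) ** 2 for se, scale in terms))


def co2_mass_to_carbon(x: float) -> float:
    """MgCO2 → MgC (× 12/44); SEs scale identically."""
    return x * CO2_TO_C


def carbon_to_co2e(x: float) -> float:
    """MgC → MgCO2e (× 44/12)."""
    return x * C_TO_CO2


def heterotrophic_respiration(
    total_mgc: float,
    total_se: float,
    partition: PartitionSpec,
    include_ratio_se: bool = False,
) -> tuple[float, float]:
    """Rh = ratio × total soil respiration.

    By default only the flux SE is scaled; with ``include_ratio_se`` the
    ratio's own SE (if given) enters in quadrature via the product rule.
    """
    rh = partition.rh_ratio * total_mgc
    if include_ratio_se and partition.rh_ratio_se is not None:
        se = math.hypot(partition.rh_ratio * total_se, total_mgc * partition.rh_ratio_se)
    else:
        se = partition.rh_ratio * total_se
    return rh, se


def onsite_co2_budget(
    rh_mgc: float, rh_se: float, inputs: CarbonInputs
) -> tuple[float, float]:
    """Onsite CO2 budget (MgC ha⁻¹ yr⁻¹) = Rh − (litterfall + root mortality);
    SE in quadrature over the three terms."""
    budget = rh_mgc - (inputs.litterfall + inputs.root_mortality)
    se = propagate_se([(rh_se, 1.0), (inputs.litterfall_se, 1.0), (inputs.root_mortality_se, 1.0)])
    return budget, se


def peat_carbon_budget(
    onsite_co2e: float, onsite_se: float,
    ch4_co2e: float, ch4_se: float,
    fluvial_co2e: float, fluvial_se: float,
) -> tuple[float, float]:
    """Peat carbon budget (MgCO2e ha⁻¹ yr⁻¹): onsite budget plus the CH4 and
    fluvial loss terms; SE in quadrature."""
    total = onsite_co2e + ch4_co2e + fluvial_co2e
    se = propagate_se([(onsite_se, 1.0), (ch4_se, 1.0), (fluvial_se, 1.0)])
    return total, se


def total_carbon_loss(
    co2: AnnualFlux, ch4_co2e: AnnualFlux, fluvial: FluvialExport
) -> LandscapeTotal:
    """Landscape total carbon loss = CO2 + CH4(CO2e) + fluvial export, all in
    MgCO2e ha⁻¹ yr⁻¹, with the fluvial share of the total in percent."""
    total = co2.mean + ch4_co2e.mean + fluvial.j_mgco2e_ha_yr
    se = propagate_se([(co2.se, 1.0), (ch4_co2e.se, 1.0), (fluvial.j_co2e_se, 1.0)])
    frac = 100.0 * fluvial.j_mgco2e_ha_yr / total if total != 0 else 0.0
    return LandscapeTotal(
        co2_mean=co2.mean, co2_se=co2.se,
        ch4_mean=ch4_co2e.mean, ch4_se=ch4_co2e.se,
        fluvial=fluvial.j_mgco2e_ha_yr, fluvial_se=fluvial.j_co2e_se,
        total_loss=total, total_se=se, fluvial_fraction=frac,
    )


def site_budget(
    co2: AnnualFlux,
    ch4_co2e: AnnualFlux,
    fluvial: FluvialExport,
    partition: PartitionSpec,
    inputs: CarbonInputs,
    include_ratio_se: bool = False,
) -> BudgetResult:
    """Full per-site ledger from the annual CO2 flux down to the peat carbon
    budget. The fluvial term is shared between sites (one river outlet)."""
    if co2.site != ch4_co2e.site or co2.site != partition.site:
        raise ValueError("site labels disagree")
    total_c = co2_mass_to_carbon(co2.mean)
    total_c_se = co2_mass_to_carbon(co2.se)
    rh, rh_se = heterotrophic_respiration(total_c, total_c_se, partition, include_ratio_se)
    onsite_c, onsite_c_se = onsite_co2_budget(rh, rh_se, inputs)
    onsite_e, onsite_e_se = carbon_to_co2e(onsite_c), carbon_to_co2e(onsite_c_se)
    peat, peat_se = peat_carbon_budget(
        onsite_e, onsite_e_se, ch4_co2e.mean, ch4_co2e.se,
        fluvial.j_mgco2e_ha_yr, fluvial.j_co2e_se,
    )
    return BudgetResult(
        site=co2.site,
        total_soil_resp_mgc=total_c, total_soil_resp_se=total_c_se,
        rh_mgc=rh, rh_se=rh_se,
        onsite_mgc=onsite_c, onsite_mgc_se=onsite_c_se,
        onsite_mgco2e=onsite_e, onsite_mgco2e_se=onsite_e_se,
        ch4_co2e=ch4_co2e.mean, ch4_co2e_se=ch4_co2e.se,
        fluvial_co2e=fluvial.j_mgco2e_ha_yr, fluvial_co2e_se=fluvial.j_co2e_se,
        peat_budget_co2e=peat, peat_budget_co2e_se=peat_se,
    )
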