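"""Physical constants and unit-conversion factors used across the pipeline."""

#: Molar gas constant (J mol⁻¹ K⁻¹).
R_GAS = 8.314462618

#: Molar masses (g mol⁻¹).
MOLAR_MASS = {"CO2": 44.01, "CH4": 16.04}

#: Seconds in the 365-day accounting year.
SECONDS_PER_YEAR = 31_536_000

#: 100-year global warming potential of CH4 (AR6, fossil-free).
GWP100_CH4 = 27.0

#: Mass ratio CO2 → C (stoichiometric; 44/12 kept exact so budget tables
#: round the way field reports print them).
CO2_TO_C = 12.0 / 44.0
C_TO_CO2 = 44.0 / 12.0

#: Default QC thresholds on the linear-fit coefficient of determination.
#: A record passes only if R² is strictly above the gas's threshold.
R2_THRESHOLDS = {"CO2": 0.9, "CH4": 0.7}

#: Ambient-like baseline mole fractions (µmol mol⁻¹).
BASELINE_PPM = {"CO2": 420.0, "CH4": 2.0}

GASES = ("CO2", "CH4")


def umol_to_mg_ha_yr(gas: str, seconds_per_year: float = SECONDS_PER_YEAR) -> float:
    """Factor converting an areal molar flux (µmol m⁻² s⁻¹) to a mass flux
    (Mg gas ha⁻¹ yr⁻¹).

    Chain: µmol→mol (1e-6) × molar mass (g mol⁻¹) × s yr⁻¹ × g→Mg (1e-6)
    × m⁻²→ha⁻¹ (1e4).
    """
    return MOLAR_MASS[gas] * 1e-6 * seconds_per_year * 1e-6 * 1e4


def mg_ha_yr_to_umol(gas: str, seconds_per_year: float = SECONDS_PER_YEAR) -> float:
    """Inverse of :func:`umol_to_mg_ha_yr`."""
    return 1.0 / umol_to_mg_ha_yr(gas, seconds_per_year)
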