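# Site-level annual summary inputs for the Muara Siran (East Kalimantan)
# undrained peat-swamp campaign, Oct 2022 - Sep 2023: measured annual gas
# fluxes and water-quality means, the station water balance, and the
# Southeast-Asia literature values used for respiration partitioning and
# carbon inputs. Feeding these into the budget chain reproduces the
# campaign's headline accounting without the raw field records.

[sites.PPSF]
description = "pristine peat swamp forest"
co2_mgco2_ha_yr = 12.61
co2_se = 0.41
ch4_co2e_ha_yr = 0.70
ch4_co2e_se = 0.04
n = 360
rh_ratio = 0.54            # heterotrophic share of total soil respiration
litterfall_mgc = 6.7       # literature, undegraded undrained SEA peatlands
litterfall_se = 0.6
root_mortality_mgc = 2.0
root_mortality_se = 1.5

[sites.SPSF]
description = "secondary peat swamp forest with historical logging"
co2_mgco2_ha_yr = 9.43
co2_se = 0.27
ch4_co2e_ha_yr = 0.46
ch4_co2e_se = 0.02
n = 360
rh_ratio = 0.81
litterfall_mgc = 6.9       # literature, degraded undrained SEA peatlands
litterfall_se = 0.6
root_mortality_mgc = 1.2
root_mortality_se = 1.0

[water_balance]
p_mm_yr = 2130.0           # annual rainfall, station year
eta_mm_yr = 1282.0         # annual actual evapotranspiration (kc * ET0)
kc = 1.0

[water_quality]
doc_mg_l = 37.10
doc_se = 0.66
poc_mg_l = 17.20
poc_se = 1.55
toc_mg_l = 54.20           # campaign-reported annual mean TOC
toc_se = 2.07
n = 36

[options]
gwp100 = 27.0
se_rule = "quadrature"
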