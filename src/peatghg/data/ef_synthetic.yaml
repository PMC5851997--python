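# Synthetic default emission-factor table.
#
# Per-gas annual fluxes per hectare for drained peatland, by land use
# (CL cropland, GL grassland, FL forest land) and climate zone. These
# are synthetic stand-in values with realistic orders of magnitude for
# drained-organic-soil fluxes (CO2 as t CO2, CH4 as t CH4, N2O as
# t N2O, DOC as t C, all ha-1 a-1); replace with an authoritative table
# for production inventories. Mixed classes are derived at load time.
emission_factors:
  # --- tropical ---
  - {landuse: CL, climate: tropical, gas: CO2, min: 20.0, mean: 51.0, max: 80.0, unit: t_CO2_ha_a}
  - {landuse: CL, climate: tropical, gas: CH4, min: 0.0, mean: 0.005, max: 0.03, unit: t_CH4_ha_a}
  - {landuse: CL, climate: tropical, gas: N2O, min: 0.0, mean: 0.008, max: 0.02, unit: t_N2O_ha_a}
  - {landuse: CL, climate: tropical, gas: DOC, min: 0.4, mean: 0.82, max: 1.3, unit: t_C_ha_a}
  - {landuse: GL, climate: tropical, gas: CO2, min: 9.0, mean: 19.0, max: 29.0, unit: t_CO2_ha_a}
  - {landuse: GL, climate: tropical, gas: CH4, min: 0.001, mean: 0.14, max: 0.5, unit: t_CH4_ha_a}
  - {landuse: GL, climate: tropical, gas: N2O, min: 0.0, mean: 0.006, max: 0.015, unit: t_N2O_ha_a}
  - {landuse: GL, climate: tropical, gas: DOC, min: 0.4, mean: 0.82, max: 1.3, unit: t_C_ha_a}
  - {landuse: FL, climate: tropical, gas: CO2, min: 4.0, mean: 19.0, max: 33.0, unit: t_CO2_ha_a}
  - {landuse: FL, climate: tropical, gas: CH4, min: 0.0, mean: 0.003, max: 0.02, unit: t_CH4_ha_a}
  - {landuse: FL, climate: tropical, gas: N2O, min: 0.0, mean: 0.004, max: 0.01, unit: t_N2O_ha_a}
  - {landuse: FL, climate: tropical, gas: DOC, min: 0.4, mean: 0.82, max: 1.3, unit: t_C_ha_a}
  # --- temperate ---
  - {landuse: CL, climate: temperate, gas: CO2, min: 22.0, mean: 29.0, max: 37.0, unit: t_CO2_ha_a}
  - {landuse: CL, climate: temperate, gas: CH4, min: 0.0, mean: 0.004, max: 0.01, unit: t_CH4_ha_a}
  - {landuse: CL, climate: temperate, gas: N2O, min: 0.008, mean: 0.021, max: 0.036, unit: t_N2O_ha_a}
  - {landuse: CL, climate: temperate, gas: DOC, min: 0.1, mean: 0.31, max: 0.5, unit: t_C_ha_a}
  - {landuse: GL, climate: temperate, gas: CO2, min: 8.0, mean: 13.0, max: 20.0, unit: t_CO2_ha_a}
  - {landuse: GL, climate: temperate, gas: CH4, min: 0.01, mean: 0.06, max: 0.2, unit: t_CH4_ha_a}
  - {landuse: GL, climate: temperate, gas: N2O, min: 0.005, mean: 0.013, max: 0.025, unit: t_N2O_ha_a}
  - {landuse: GL, climate: temperate, gas: DOC, min: 0.1, mean: 0.31, max: 0.5, unit: t_C_ha_a}
  - {landuse: FL, climate: temperate, gas: CO2, min: 5.0, mean: 9.0, max: 14.0, unit: t_CO2_ha_a}
  - {landuse: FL, climate: temperate, gas: CH4, min: 0.0, mean: 0.01, max: 0.05, unit: t_CH4_ha_a}
  - {landuse: FL, climate: temperate, gas: N2O, min: 0.001, mean: 0.004, max: 0.01, unit: t_N2O_ha_a}
  - {landuse: FL, climate: temperate, gas: DOC, min: 0.1, mean: 0.31, max: 0.5, unit: t_C_ha_a}
  # --- boreal + polar (shared factors) ---
  - {landuse: CL, climate: boreal_polar, gas: CO2, min: 20.0, mean: 29.0, max: 37.0, unit: t_CO2_ha_a}
  - {landuse: CL, climate: boreal_polar, gas: CH4, min: 0.0, mean: 0.002, max: 0.01, unit: t_CH4_ha_a}
  - {landuse: CL, climate: boreal_polar, gas: N2O, min: 0.01, mean: 0.02, max: 0.03, unit: t_N2O_ha_a}
  - {landuse: CL, climate: boreal_polar, gas: DOC, min: 0.05, mean: 0.12, max: 0.3, unit: t_C_ha_a}
  - {landuse: GL, climate: boreal_polar, gas: CO2, min: 9.0, mean: 16.0, max: 24.0, unit: t_CO2_ha_a}
  - {landuse: GL, climate: boreal_polar, gas: CH4, min: 0.0, mean: 0.005, max: 0.02, unit: t_CH4_ha_a}
  - {landuse: GL, climate: boreal_polar, gas: N2O, min: 0.002, mean: 0.015, max: 0.03, unit: t_N2O_ha_a}
  - {landuse: GL, climate: boreal_polar, gas: DOC, min: 0.05, mean: 0.12, max: 0.3, unit: t_C_ha_a}
  - {landuse: FL, climate: boreal_polar, gas: CO2, min: 1.0, mean: 2.0, max: 4.0, unit: t_CO2_ha_a}
  - {landuse: FL, climate: boreal_polar, gas: CH4, min: 0.0, mean: 0.002, max: 0.01, unit: t_CH4_ha_a}
  - {landuse: FL, climate: boreal_polar, gas: N2O, min: 0.0, mean: 0.002, max: 0.006, unit: t_N2O_ha_a}
  - {landuse: FL, climate: boreal_polar, gas: DOC, min: 0.05, mean: 0.12, max: 0.3, unit: t_C_ha_a}
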