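# Default run configuration. User YAML overrides these keys.
gwp:
  gwp_ch4: 28.0
  gwp_n2o: 265.0
  horizon: GWP100
ef_table: null          # path to a per-gas EF YAML; null = packaged synthetic defaults
cropland_threshold: 0.5
constants:
  tropical_peat_cn: 29.7
  northern_peat_cn: 49.0
  mineral_cn: 10.7
mineral_soil:
  agricultural_area_mha: 4923.0
  arable_area_mha: 1563.0
  pasture_area_mha: 3360.0
  soil_c_percent: 1.35
  seq_min_gt: 24.0
  seq_max_gt: 64.0
  horizon_years: 63.0
trajectory:
  dt: 0.5
  horizon: 1200.0
  sink_t_seq: 63.0
  sink_s_max: [24.0, 44.0, 64.0]
scenario:
  multiplier: 2.0
  half_saturation_years: 60.0
world:
  shape: [256, 256]
  n_countries: 6
  cell_area_ha: 100.0
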