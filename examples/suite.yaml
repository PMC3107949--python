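# Scenario suite for `footmech run --config examples/suite.yaml --out results/`
# Every block is optional; omitted values take package defaults.
suite:
  seed: 0
  scenarios: [normal, flatfoot, MCO, Evans, CCDA, Evans_MCO, CCDA_MCO]
anatomy:
  foot_length_mm: 250.0
  arch_height_fraction: 0.24
  foot_width_mm: 90.0
load:
  axial_load_N: 690.0
  achilles_load_N: 345.0
surgery:
  mco_offset_mm: 10.0
  evans_cut_offset_mm: 10.0
  wedge_width_mm: 10.0
  wedge_depth_mm: 25.0
  ccda_resection_mm: 3.0
solver:
  tolerance_N: 0.5
  n_ramp_stages: 10
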