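schema_version: 1
provenance: calibrated to published base-case anchors (see fit report)
objective: 0.03495870676828727
unprinted:
  early_dwell_cycles: 1
  screen_sensitivity_early: 0.97604
  p_incidental_early_percycle: 0.002
  p_symptomatic_detect_percycle: 1.0
  cost_care_comp_annual: 1236.010191
  cost_care_decomp_annual: 3830.836718
  cost_diagnostic_workup: 1000.0
  cpi_adjust: 1.0
  p_false_positive: 0.0
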