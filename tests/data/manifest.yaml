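seed: 7
criteria:
  dta_mm: 2.0
  dd_pct: 2.0
  threshold_pct: 10.0
  normalization: global
measurement:
  grid_spacing_mm: 5.0
  noise_pct: 0.0
penumbra_sigma_mm: 2.0
plans:
  - plan_id: sweep5
    pattern:
      kind: sweeping_gap
      gap_mm: 5.0
      sweep_extent_mm: 60.0
      field_size_mm: [60.0, 60.0]
      mu: 100.0
    truth: {dlg_mm: 1.0, transmission_pct: 1.5}
  - plan_id: measured_file
    measured: example_plane.txt
    calculated_template: "calc_{dlg:.2f}.txt"
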