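# Demo run: small synthetic explant cohort + drug-response experiment
# + a rendered 3-D stack series, through every pipeline stage.
seed: 42
cohort:
  n_cells: 24
  class_mix: {LNv: 0.4, DN1: 0.35, DN2: 0.25}
  rhythmic_fraction: 0.6
  sampling_interval_hr: 3.0
  duration_hr: 48.0
response:
  groups: [Vehicle, PDF, PDF+TTX]
  classes: [LNv, DN1, DN2]
  n_per_group_class: 12
  baseline_hr: 1.0
  duration_hr: 8.0
  sampling_interval_hr: 1.0
  effect:
    onset_hr: 1.0
    affected_groups: [PDF]
    affected_classes: [LNv, DN1]
    effect_shape: ramp
    effect_size: 0.1
    blocked_by: [TTX]
stacks:
  enabled: true
  shape: [12, 48, 48]
  n_cells: 3
  background_level: 10.0
  peak_intensity: 60.0
  radius_voxels: 2.5
rhythms:
  band_hr: [18.0, 36.0]
  order_rule: n/3
  n_frequencies: 2048
respond:
  reference_group: Vehicle
  family: panel
  alpha: 0.05
report:
  heatmap_window_hr: 24.0
  ceiling: 3.0
  render_png: true
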