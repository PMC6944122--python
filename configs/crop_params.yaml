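# Per-crop standard crop coefficients, heights and season calendars.
# These mirror the package defaults; edit to override per study region.
# stage_lengths are [initial, development, mid-season, late] in days,
# start_day is the planting day of year.
wheat:
  kc_ini: 0.30
  kc_mid: 1.15
  kc_end: 0.25
  height_m: 1.0
  start_day: 91
  stage_lengths: [20, 25, 60, 30]
corn:
  kc_ini: 0.30
  kc_mid: 1.20
  kc_end: 0.35
  height_m: 2.0
  start_day: 110
  stage_lengths: [30, 40, 50, 30]
cotton:
  kc_ini: 0.35
  kc_mid: 1.15
  kc_end: 0.70
  height_m: 1.3
  start_day: 100
  stage_lengths: [30, 50, 60, 55]
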