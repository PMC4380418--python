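# Reference four-segment rotary-zone cycler: 55 g aluminum blocks spanning
# 73.6 degrees on a 7.62 cm wheel, FEP 406/794 um sample capillary (~4 uL
# engaged), stock stepper settings, 270-degree harness twist limit.
# steps_per_segment is calibrated from the observed 1.32 s single-segment
# transition under the stock motion profile.
schema_version: 1
name: reference-rztc
materials: {}   # handbook defaults; override entries here as needed
capillary:
  inner_diameter_um: 406.0
  outer_diameter_um: 794.0
  wall_material: fep
blocks:
  - {id: load,   mass_g: 55.0, material: aluminum, setpoint: null}
  - {id: anneal, mass_g: 55.0, material: aluminum, setpoint: 60.0}
  - {id: extend, mass_g: 55.0, material: aluminum, setpoint: 72.0}
  - {id: denature, mass_g: 55.0, material: aluminum, setpoint: 98.0}
layout:
  num_segments: 4
  steps_per_segment: 2658.56
  segment_order: [load, anneal, extend, denature]
  arc_span: 73.6
  harness_twist_limit: 270.0
  gear_ratio: 26.85
motion:
  acceleration: 6103.52
  max_velocity: 4000.0
sample_volume_ul: 4.0
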