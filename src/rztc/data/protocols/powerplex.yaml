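# Two-stage STR multiplex: five temperatures on four blocks via a mid-run
# setpoint change (the 96 degC hot-start block re-targets to 90 degC for
# stage-2 denaturation; stabilization runs concurrently with stage 1).
schema_version: 1
name: powerplex-32-cycle
hot_start: {temp: 96.0, duration: 120.0}
stages:
  - cycles: 10
    steps:
      - {temp: 94.0, dwell: 30.0, label: denature}
      - {temp: 60.0, dwell: 30.0, label: anneal}
      - {temp: 70.0, dwell: 45.0, label: extend}
  - cycles: 22
    steps:
      - {temp: 90.0, dwell: 30.0, label: denature}
      - {temp: 60.0, dwell: 30.0, label: anneal}
      - {temp: 70.0, dwell: 45.0, label: extend}
final_step: {temp: 60.0, duration: 1800.0}
setpoint_changes:
  - {from_temp: 96.0, to_temp: 90.0, after_stage: 0, stabilization_time: 1080.0}
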