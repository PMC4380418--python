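# Minimal protocol: water flushes and manual tip cleaning only.
schema_version: 1
id: E
description: Three full-syringe water flushes with manual inlet and outlet tip cleaning; no bleach.
valve_rotation_wash: false
final_inlet_flush: false
dedicated_wheel_wash: none
inlet_wash: false
steps:
  - {action: flush, reagent: water, volume: 500, consumes: true, flow_path: wheel, note: "full syringe of water through the wheel"}
  - {action: manual, duration: 75, note: "inlet capillary tip agitation (5 x 15 s)"}
  - {action: flush, reagent: water, volume: 500, consumes: true, flow_path: wheel}
  - {action: manual, duration: 75, note: "outlet tube tip agitation (5 x 15 s)"}
  - {action: flush, reagent: water, volume: 500, consumes: true, flow_path: wheel}
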