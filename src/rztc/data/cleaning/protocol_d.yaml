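# Inlet cleaning only: no dedicated wheel wash.  The wheel is set to its
# highest-temperature position at the outset so all inlet-cleaning effluent
# passes through the preheated reactor.
schema_version: 1
id: D
description: Inlet wash only; wheel preheated; no dedicated wheel wash.
valve_rotation_wash: false
final_inlet_flush: false
dedicated_wheel_wash: none
inlet_wash: true
steps:
  - {action: manual, duration: 2.7, note: "rotate hottest block against reactor at outset"}
  - {action: flush, reagent: water, volume: 500, consumes: true, flow_path: wheel, note: "prime reactor; full syringe of water to waste"}
  - {action: aspirate, reagent: air, volume: 200, flow_path: inlet, note: "air purge of sample introduction line"}
  - {action: flush, reagent: water, volume: 500, consumes: true, flow_path: wheel, note: "make room for bleach in reagent loop (reconstructed volume)"}
  - {action: aspirate, reagent: bleach, volume: 30, repetitions: 3, consumes: true, flow_path: wheel, note: "load inlet-wash bleach (reconstructed 3 x 30 uL)"}
  - {action: dispense, reagent: bleach, volume: 30, repetitions: 3, flow_path: inlet, note: "push bleach to inlet tip"}
  - {action: incubate, duration: 15, repetitions: 3, note: "hold bleach at inlet tip"}
  - {action: aspirate, reagent: bleach, volume: 30, repetitions: 3, flow_path: inlet, note: "withdraw past upstream valve"}
  - {action: dispense, reagent: bleach, volume: 30, repetitions: 3, flow_path: wheel, note: "discard through preheated wheel"}
  - {action: flush, reagent: water, volume: 500, consumes: true, flow_path: wheel, note: "flush remaining bleach and syringe water"}
  - {action: aspirate, reagent: water, volume: 30, repetitions: 3, consumes: true, flow_path: wheel, note: "identical three-stage wash with water"}
  - {action: dispense, reagent: water, volume: 30, repetitions: 3, flow_path: inlet}
  - {action: incubate, duration: 15, repetitions: 3}
  - {action: aspirate, reagent: water, volume: 30, repetitions: 3, flow_path: inlet}
  - {action: dispense, reagent: water, volume: 30, repetitions: 3, flow_path: wheel}
  - {action: dispense, reagent: water, volume: 180, consumes: true, flow_path: inlet, note: "push water to inlet tip for manual clean (reconstructed)"}
  - {action: manual, duration: 75, note: "tip agitation in bleach, water, decontaminant 1, decontaminant 2, water (5 x 15 s)"}
  - {action: dispense, reagent: water, volume: 30, consumes: true, flow_path: inlet, note: "3 x 10 uL purge droplets"}
  - {action: aspirate, reagent: water, volume: 30, flow_path: inlet, note: "withdraw remaining water past valve"}
  - {action: dispense, reagent: water, volume: 30, flow_path: wheel, note: "discard"}
  - {action: flush, reagent: water, volume: 500, consumes: true, flow_path: wheel, note: "closing wheel flush (reconstructed volume)"}
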