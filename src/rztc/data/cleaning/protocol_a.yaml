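# Baseline (most conservative) between-run cleaning protocol.
# Per-step volumes not individually stated in the source narrative are
# reconstructed so ledger totals match the feature-comparison table
# (reconstructed steps are annotated in their notes).
schema_version: 1
id: A
description: Full inlet wash, full dedicated wheel wash, valve rotation wash, final inlet flush.
valve_rotation_wash: true
final_inlet_flush: true
dedicated_wheel_wash: full
inlet_wash: true
steps:
  # --- inlet cleaning ---
  - {action: flush, reagent: water, volume: 500, consumes: true, flow_path: wheel, note: "prime reactor; full syringe of water to waste"}
  - {action: aspirate, reagent: air, volume: 200, flow_path: inlet, note: "air purge of sample introduction line"}
  - {action: flush, reagent: water, volume: 500, consumes: true, flow_path: wheel, note: "make room for bleach in reagent loop (reconstructed volume)"}
  - {action: aspirate, reagent: bleach, volume: 30, repetitions: 3, consumes: true, flow_path: wheel, note: "load inlet-wash bleach (reconstructed 3 x 30 uL)"}
  - {action: dispense, reagent: bleach, volume: 30, repetitions: 3, flow_path: inlet, note: "push bleach to inlet tip"}
  - {action: incubate, duration: 15, repetitions: 3, note: "hold bleach at inlet tip"}
  - {action: aspirate, reagent: bleach, volume: 30, repetitions: 3, flow_path: inlet, note: "withdraw past upstream valve"}
  - {action: dispense, reagent: bleach, volume: 30, repetitions: 3, flow_path: wheel, note: "discard through wheel"}
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
  # --- dedicated wheel wash (full) ---
  - {action: manual, duration: 2.7, note: "rotate hottest block against reactor"}
  - {action: aspirate, reagent: bleach, volume: 90, consumes: true, flow_path: wheel, note: "load 90 uL wheel-wash bleach"}
  - {action: dispense, reagent: bleach, volume: 90, flow_path: wheelwash_slow, note: "push through heated capillary in 30 uL increments at varied slow rates"}
  - {action: incubate, duration: 10, repetitions: 2, note: "dwells between increments"}
  - {action: flush, reagent: water, volume: 500, consumes: true, flow_path: wheel}
  - {action: aspirate, reagent: bleach, volume: 90, consumes: true, flow_path: wheel, note: "second 90 uL bleach volume"}
  - {action: dispense, reagent: bleach, volume: 90, flow_path: wheel, note: "span upstream and downstream valves"}
  # --- valve rotation wash (bleach) ---
  - {action: actuate_valve, repetitions: 24, note: "3 sets of 8 actuations (4 per valve)"}
  - {action: dispense, reagent: bleach, volume: 10, repetitions: 2, flow_path: wheel, note: "advance slug between sets (driven by following flush water)"}
  - {action: incubate, duration: 10, repetitions: 2}
  - {action: flush, reagent: water, volume: 500, consumes: true, flow_path: wheel}
  - {action: dispense, reagent: water, volume: 90, consumes: true, flow_path: wheel, note: "water slug spanning valves to remove residual bleach"}
  # --- valve rotation wash (water) ---
  - {action: actuate_valve, repetitions: 24}
  - {action: dispense, reagent: water, volume: 10, repetitions: 2, flow_path: wheel, note: "advance slug between sets (counted in following flush)"}
  - {action: incubate, duration: 10, repetitions: 2}
  - {action: flush, reagent: water, volume: 500, consumes: true, flow_path: wheel}
  - {action: manual, duration: 75, note: "outlet tube tip agitation (5 x 15 s)"}
  - {action: flush, reagent: water, volume: 410, consumes: true, flow_path: wheel, note: "wheel flush (reconstructed volume)"}
  # --- final inlet flush ---
  - {action: flush, reagent: water, volume: 500, consumes: true, flow_path: wheel, note: "final 500 uL inlet flush"}
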