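# Calibrated per-step timing for cleaning duration estimates.
# Flow rates in uL/s per flow path; fixed durations in seconds.
# The rates were calibrated once against the observed protocol durations
# (a fixture of this package, not a measured truth); override for other
# pump/tubing combinations.
schema_version: 1
flow_rates:
  wheel: 7.1429          # syringe -> reactor -> waste
  inlet: 2.141           # fine sample-introduction capillary
  wheelwash_slow: 2.5    # incremental bleach push, full wheel wash
  wheelwash_fast: 15.0   # abbreviated wheel wash
valve_actuation_time: 2.0
manual_agitation_time: 15.0
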