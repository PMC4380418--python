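# Rapid single-plex amplification: 26 cycles with a hot-start and final
# elongation; three heated zones plus an unheated load segment.
schema_version: 1
name: phusion-26-cycle
hot_start: {temp: 98.0, duration: 30.0}
stages:
  - cycles: 26
    steps:
      - {temp: 98.0, dwell: 5.0, label: denature}
      - {temp: 60.0, dwell: 10.0, label: anneal}
      - {temp: 72.0, dwell: 15.0, label: extend}
final_step: {temp: 72.0, duration: 300.0}
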