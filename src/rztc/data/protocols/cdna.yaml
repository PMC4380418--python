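# Second-strand cDNA synthesis cycling: denature/anneal/extend with a long
# extension dwell and final extension.
schema_version: 1
name: cdna-second-strand
hot_start: {temp: 95.0, duration: 60.0}
stages:
  - cycles: 12
    steps:
      - {temp: 95.0, dwell: 30.0, label: denature}
      - {temp: 55.0, dwell: 30.0, label: anneal}
      - {temp: 68.0, dwell: 180.0, label: extend}
final_step: {temp: 68.0, duration: 420.0}
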