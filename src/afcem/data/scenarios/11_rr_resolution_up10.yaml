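scenario_id: 11_rr_resolution_up10
label: Increase RR of symptom resolution by 10%
transforms:
- path: clinical.rr_resolution_by_count
  op: scale
  value: 1.1
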