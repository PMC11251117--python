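scenario_id: 14_stroke_rr_up10
label: Increase health-state-specific stroke RR by 10%
transforms:
- path: events.stroke_rr_by_state
  op: scale
  value: 1.1
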