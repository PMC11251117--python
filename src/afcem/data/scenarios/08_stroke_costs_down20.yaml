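scenario_id: 08_stroke_costs_down20
label: Stroke event and ongoing costs decreased by 20%
transforms:
- path: costs.stroke_event
  op: scale
  value: 0.8
- path: costs.stroke_followup_per_cycle
  op: scale
  value: 0.8
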