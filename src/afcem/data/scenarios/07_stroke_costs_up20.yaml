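scenario_id: 07_stroke_costs_up20
label: Stroke event and ongoing costs increased by 20%
transforms:
- path: costs.stroke_event
  op: scale
  value: 1.2
- path: costs.stroke_followup_per_cycle
  op: scale
  value: 1.2
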