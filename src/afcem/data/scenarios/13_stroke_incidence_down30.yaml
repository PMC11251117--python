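scenario_id: 13_stroke_incidence_down30
label: Decrease the incidence rate of stroke by 30%
transforms:
- path: events.stroke_risk_by_score
  op: scale
  value: 0.7
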