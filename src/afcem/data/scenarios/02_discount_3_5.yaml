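scenario_id: 02_discount_3_5
label: Discount rate 3.5%
transforms:
- path: settings.discount_rate_costs
  op: set
  value: 0.035
- path: settings.discount_rate_qalys
  op: set
  value: 0.035
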