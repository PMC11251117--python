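scenario_id: 15_horizon_10y
label: Time horizon 10 years
transforms:
- path: settings.horizon_years
  op: set
  value: 10
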