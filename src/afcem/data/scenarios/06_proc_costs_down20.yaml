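scenario_id: 06_proc_costs_down20
label: Cryoablation procedure-related costs decreased by 20%
transforms:
- path: costs.index_procedure
  op: scale
  value: 0.8
- path: costs.reablation_procedure
  op: scale
  value: 0.8
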