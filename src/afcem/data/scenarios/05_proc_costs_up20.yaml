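scenario_id: 05_proc_costs_up20
label: Cryoablation procedure-related costs increased by 20%
transforms:
- path: costs.index_procedure
  op: scale
  value: 1.2
- path: costs.reablation_procedure
  op: scale
  value: 1.2
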