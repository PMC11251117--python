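scenario_id: 12_reablation_success_down30
label: Decreased the probability of successful re-ablation by 30%
transforms:
- path: clinical.per_arm.cryo.reablation_success
  op: scale
  value: 0.7
- path: clinical.per_arm.cryo.year1.reablation_success
  op: scale
  value: 0.7
- path: clinical.per_arm.aad.reablation_success
  op: scale
  value: 0.7
- path: clinical.per_arm.aad.year1.reablation_success
  op: scale
  value: 0.7
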