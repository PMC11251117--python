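scenario_id: 03_blanking_period
label: Blanking period included
note: per-arm AF-recurrence inputs scaled by the blanked/unblanked ratio estimated
  once from the synthetic patient-level pipeline (20 seeded replicates of generate
  -> exclude -> blank -> refit)
transforms:
- path: clinical.per_arm.cryo.recurrence
  op: scale
  value: 0.767
- path: clinical.per_arm.cryo.year1.recurrence
  op: scale
  value: 0.767
- path: clinical.per_arm.aad.recurrence
  op: scale
  value: 0.762
- path: clinical.per_arm.aad.year1.recurrence
  op: scale
  value: 0.762
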