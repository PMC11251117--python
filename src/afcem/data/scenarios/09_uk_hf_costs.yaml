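scenario_id: 09_uk_hf_costs
label: UK-based heart failure costs (converted to Euros)
note: NYHA-stratified per-cycle costs; placeholder values (assumption)
transforms:
- path: costs.hf_per_cycle.I
  op: set
  value: 1500
- path: costs.hf_per_cycle.II
  op: set
  value: 3000
- path: costs.hf_per_cycle.III
  op: set
  value: 5500
- path: costs.hf_per_cycle.IV
  op: set
  value: 8000
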