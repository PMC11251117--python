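scenario_id: 00_base_case
label: Deterministic base case
transforms: []
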