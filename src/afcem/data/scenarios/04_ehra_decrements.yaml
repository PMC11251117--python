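scenario_id: 04_ehra_decrements
label: EHRA class-based decrements
note: EHRA-stratified utility decrements; placeholder values (assumption)
transforms:
- path: utilities.state_decrements.ST_EPISODIC
  op: set
  value: 0.1
- path: utilities.state_decrements.LT_PERSISTENT
  op: set
  value: 0.11
- path: utilities.state_decrements.PERMANENT
  op: set
  value: 0.14
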