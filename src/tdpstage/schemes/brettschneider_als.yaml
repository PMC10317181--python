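# PROVISIONAL region memberships for the four-stage ALS TDP-43 scheme
# (motor-onset caudorostral spread).  Edit to match the exact published
# per-stage region lists before drawing scientific conclusions.
name: Brettschneider ALS
stages:
  - label: I
    regions: [motor_cortex, spinal_cord, medulla]
  - label: II
    regions: [midbrain, pons]
  - label: III
    regions: [middle_frontal, caudate_putamen]
  - label: IV
    regions: [superior_middle_temporal, ca_subiculum]
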