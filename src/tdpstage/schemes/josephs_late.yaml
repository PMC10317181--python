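# PROVISIONAL region memberships for a six-stage medial-temporal TDP-43
# scheme.  Edit to match the exact published per-stage region lists.
name: Josephs LATE-NC
stages:
  - label: I
    regions: [amygdala]
  - label: II
    regions: [entorhinal_cortex, ca_subiculum]
  - label: III
    regions: [dentate_gyrus, occipital_cortex]
  - label: IV
    regions: [superior_middle_temporal, anterior_cingulate]
  - label: V
    regions: [substantia_nigra, midbrain]
  - label: VI
    regions: [middle_frontal]
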