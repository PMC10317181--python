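# PROVISIONAL region memberships for a five-stage limbic-onset TDP-43
# scheme.  Edit to match the exact published per-stage region lists.
name: Rush LATE-NC
stages:
  - label: I
    regions: [amygdala]
  - label: II
    regions: [entorhinal_cortex]
  - label: III
    regions: [ca_subiculum, dentate_gyrus]
  - label: IV
    regions: [anterior_cingulate, superior_middle_temporal]
  - label: V
    regions: [middle_frontal, orbitofrontal_cortex]
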