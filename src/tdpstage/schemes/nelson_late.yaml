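# PROVISIONAL region memberships for the three-stage LATE-NC scheme
# (amygdala -> hippocampus -> middle frontal gyrus).  Edit to match the
# exact published per-stage region lists.
name: Nelson LATE-NC
stages:
  - label: I
    regions: [amygdala]
  - label: II
    regions: [ca_subiculum, entorhinal_cortex, dentate_gyrus]
  - label: III
    regions: [middle_frontal]
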