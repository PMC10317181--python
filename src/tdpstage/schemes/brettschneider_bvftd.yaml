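# PROVISIONAL region memberships for the four-stage bvFTD TDP-43 scheme
# (orbitofrontal-onset rostrocaudal spread).  Edit to match the exact
# published per-stage region lists before drawing scientific conclusions.
name: Brettschneider bvFTD
stages:
  - label: I
    regions: [orbitofrontal_cortex, amygdala]
  - label: II
    regions: [middle_frontal, anterior_cingulate, caudate_putamen, thalamus]
  - label: III
    regions: [motor_cortex, spinal_cord, medulla]
  - label: IV
    regions: [occipital_cortex]
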