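# SYNTHETIC PLACEHOLDER nomogram — NOT the published visual PROMISE model.
# The published point tables and cut-offs must be obtained from their source
# publication's appendices and supplied by the user.  This file only
# exercises the scoring machinery: points are invented, round numbers.
variant: visual
cutoff: 100.0
points:
  tumour_count:
    - [0, 0.0]
    - [1, 20.0]
    - [5, 55.0]
    - [20, 90.0]
  has_locoregional_nodes: 10.0
  has_extrapelvic_nodes: 30.0
  has_bone_mets: 45.0
  has_organ_mets: 60.0
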