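# SYNTHETIC PLACEHOLDER nomogram — NOT the published quantitative PROMISE
# model.  Supply the published point tables and cut-off to reproduce
# published risk groups; these invented values only exercise the machinery.
variant: quantitative
cutoff: 120.0
points:
  tumour_count:
    - [0, 0.0]
    - [1, 15.0]
    - [5, 40.0]
    - [20, 70.0]
  has_locoregional_nodes: 10.0
  has_extrapelvic_nodes: 25.0
  has_bone_mets: 35.0
  has_organ_mets: 50.0
  total_volume:
    - [0, 0.0]
    - [10, 20.0]
    - [100, 45.0]
  suv_mean:
    - [0, 0.0]
    - [5, 10.0]
    - [15, 25.0]
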