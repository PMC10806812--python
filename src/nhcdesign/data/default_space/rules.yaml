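# Combination rules for the bundled default NHC fragment space.
# This space is a stand-in exploring the same chemistry axes (aryl ortho /
# para substitution, symmetric backbone alkylation) as published
# imidazolidin-2-ylidene designs; it is not any study's deposited space.
compatibility:
  n_aryl: [aryl_ipso]
  ortho: [r_alkyl, r_acyl]
  para: [r_alkyl, r_amino, r_nitro]
  backbone: [r_alkyl, r_backbone_alkyl]
site_classes:
  n_aryl: n_aryl
  ortho: ortho
  para: meta_para
  backbone: backbone
symmetry_groups:
  imidazolidin-2-ylidene:
    naryl: [0, 1]
    backbone_a: [2, 3]
    backbone_b: [4, 5]
hindered_rotation: true
default_capping: {}
mandatory_classes: [n_aryl]
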