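# Package defaults.
#
# similarity_threshold is the calibrated similar/dissimilar verdict cut:
# the midpoint between the lowest labeled-similar pair score (0.3333,
# astragalin vs perilloside A) and the highest labeled-dissimilar pair
# score (0.1538, oleanolic vs gallic acid) on the packaged calibration
# pairs under rule table version 1.  Recompute with
# phytoformula.pharmacophore.calibrate_threshold after any rule change.
similarity_threshold: 0.2436
compound_threshold: 4
pathway_threshold: 4
min_direct_degree: 4
degree_kinds: [targets_direct, targets_indirect]
# multi-pathway protein set asserted by curation (the packaged
# target-pathway layer is also padded to make these derivable)
pt_p_override: [PT14, PT47, PT52, PT56]
adme_windows:
  mw: [130, 725]
  logp: [-2.0, 6.5]
  logs: [-6.5, 0.5]
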