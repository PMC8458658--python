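# Default NMOSD/MS summative score model.
#
# Feature lists are the features significantly associated with each disease
# in the source cohort analysis; weights are a documented reconstruction
# (double weight on longitudinally extensive cord and bilateral optic nerve
# lesions for NMOSD and on ovoid lesions for MS, weight 1 elsewhere).
# Override freely via your own YAML file.
nmosd_features:
  longitudinal_cord_T2: 2
  bilateral_optic_nerve_T2_gd: 2
  bright_spotty_cord_T2: 1
  whole_cord_T2: 1
  cord_gd: 1
  optic_nerve_gd: 1
  nucleus_tractus_solitarius_T2: 1
  periaqueductal_T2: 1
  third_ventricle_T2: 1
  cord_swelling: 1
  central_cord_T2: 1
  optic_nerve_T2: 1
  hypothalamic_T2: 1
  normal_brain: 1
  cord_atrophy: 1
ms_features:
  ovoid_T2: 2
  dawsons_fingers: 1
  pyramidal_corpus_callosum_T2: 1
  other_corpus_callosum_T2: 1
  paty_criteria: 1
  periventricular_T2: 1
  temporal_lobe_T2: 1
  black_hole_T1: 1
  corpus_callosum_T2: 1
  splenium_T2: 1
  new_T2: 1
  inferior_temporal_lobe_T2: 1
  barkhof_criteria: 1
  nine_or_more_T2: 1
  cerebellar_T2: 1
  large_supratentorial_T2: 1
  large_T2: 1
  cortical_T2: 1
  subcortical_T2: 1
  juxtacortical_T2: 1
  cerebellar_peduncle_T2: 1
  short_cord_T2: 1
  partial_cord_T2: 1
combination_ratio: 3.5
mode: summative
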