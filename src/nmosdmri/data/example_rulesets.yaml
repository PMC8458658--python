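# Illustrative boolean rulesets for the external-criteria engine.
# These are synthetic stand-ins demonstrating the config format, NOT the
# published definitions of any named external criteria (those live in their
# original publications and should be transcribed into files like this one
# by users who need them).
letm_only: longitudinal_cord_T2
letm_not_dawsons: longitudinal_cord_T2 and not dawsons_fingers
cord_or_optic: longitudinal_cord_T2 or bilateral_optic_nerve_T2_gd or optic_chiasm_T2_gd
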