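# Illustrative decision tree for the tree engine.  NOT a fitted model:
# the published machine-learning tree's exact structure is not reproduced
# here; this example uses clinically sensible splits to demonstrate the
# engine and for end-to-end testing.
feature: longitudinal_cord_T2
yes: {leaf: NMOSD}
no:
  feature: bright_spotty_cord_T2
  yes: {leaf: NMOSD}
  no:
    feature: bilateral_optic_nerve_T2_gd
    yes: {leaf: NMOSD}
    no:
      feature: ovoid_T2
      yes: {leaf: MS}
      no:
        feature: dawsons_fingers
        yes: {leaf: MS}
        no:
          feature: central_cord_T2
          yes: {leaf: NMOSD}
          no:
            feature: cord_gd
            yes: {leaf: NMOSD}
            no:
              feature: periventricular_T2
              yes: {leaf: MS}
              no:
                feature: paty_criteria
                yes: {leaf: MS}
                no: {leaf: NMOSD}
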