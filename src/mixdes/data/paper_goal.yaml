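# Desirability goal reproducing the reported optimum formulation
# (6.0 / 2.5 / 2.0 / 2.5 / 87.0 wt%).  The study's verbal criterion does not
# determine a unique optimum; this file encodes the formulators' choices:
# both responses of both drug loads minimized, oil maximized at triple weight
# (drug payload dominates the size penalty of added oil), lecithin and
# glycerol held at their selected 2.5 wt% levels.
responses:
  ps_dtx: {goal: minimize}
  ps_ccm: {goal: minimize}
  vmd_dtx: {goal: minimize}
  vmd_ccm: {goal: minimize}
components:
  oil: {goal: maximize, weight: 3}
  lecithin: {goal: target, value: 2.5}
  glycerol: {goal: target, value: 2.5}
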