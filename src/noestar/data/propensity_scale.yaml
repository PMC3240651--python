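# Disorder-propensity scale for the stand-in windowed predictor.
# Higher = more disorder-promoting. The ranking follows the broad consensus
# of composition-based order/disorder scales (aromatics and branched
# hydrophobics strongly order-promoting; E, K, S, Q, P disorder-promoting)
# but is an editable illustrative table, not any published predictor.
name: propensity9
window: 9
propensities:
  W: -0.88
  F: -0.70
  Y: -0.51
  I: -0.49
  M: -0.40
  L: -0.33
  V: -0.12
  C: -0.02
  N: 0.01
  T: 0.06
  A: 0.06
  G: 0.17
  R: 0.18
  D: 0.19
  H: 0.30
  Q: 0.32
  S: 0.34
  K: 0.59
  E: 0.74
  P: 0.99
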