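# SYNTHETIC reference amino-acid composition for enrichment reports.
# Shaped like a database of experimentally characterized disordered
# proteins (hydrophobics rare; S/K/E/P/G common) but constructed for this
# package: it is a labelled stand-in, not a published table. Frequencies
# sum to 1. Supply your own table for real comparisons.
frequencies:
  A: 0.070
  R: 0.049
  N: 0.038
  D: 0.058
  C: 0.010
  Q: 0.052
  E: 0.070
  G: 0.080
  H: 0.021
  I: 0.037
  L: 0.058
  K: 0.080
  M: 0.017
  F: 0.025
  P: 0.090
  S: 0.100
  T: 0.062
  W: 0.005
  Y: 0.019
  V: 0.059
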