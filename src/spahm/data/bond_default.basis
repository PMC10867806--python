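# Default bond-centered fitting basis: even-tempered, l_max=2,
# 6 exponents per l spanning [0.08, 8.0] Bohr^-2, all element pairs.
pair default
S
  8.00000000  1.0
S
  3.18485736  1.0
S
  1.26791455  1.0
S
  0.50476588  1.0
S
  0.20095091  1.0
S
  0.08000000  1.0
P
  8.00000000  1.0
P
  3.18485736  1.0
P
  1.26791455  1.0
P
  0.50476588  1.0
P
  0.20095091  1.0
P
  0.08000000  1.0
D
  8.00000000  1.0
D
  3.18485736  1.0
D
  1.26791455  1.0
D
  0.50476588  1.0
D
  0.20095091  1.0
D
  0.08000000  1.0
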