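# Synthetic atom-centered density-fitting basis (registry key "cc-pVDZ/JKFIT"):
# even-tempered, uncontracted; per-element shell composition follows the
# cc-pVDZ-JKFIT pattern (H 4s3p2d; C,N,O 9s7p5d3f; S 11s9p7d3f1g) but the
# exponents are generated in-package, NOT the literature data.
element H
S
  30.00000000  1.0
S
  4.76220316  1.0
S
  0.75595263  1.0
S
  0.12000000  1.0
P
  8.00000000  1.0
P
  1.26491106  1.0
P
  0.20000000  1.0
D
  2.50000000  1.0
D
  0.35000000  1.0
element C
S
  900.00000000  1.0
S
  284.60498942  1.0
S
  90.00000000  1.0
S
  28.46049894  1.0
S
  9.00000000  1.0
S
  2.84604989  1.0
S
  0.90000000  1.0
S
  0.28460499  1.0
S
  0.09000000  1.0
P
  90.00000000  1.0
P
  29.85833815  1.0
P
  9.90578175  1.0
P
  3.28633535  1.0
P
  1.09027236  1.0
P
  0.36170801  1.0
P
  0.12000000  1.0
D
  20.00000000  1.0
D
  6.16014058  1.0
D
  1.89736660  1.0
D
  0.58440225  1.0
D
  0.18000000  1.0
F
  5.00000000  1.0
F
  1.22474487  1.0
F
  0.30000000  1.0
element N
S
  1200.00000000  1.0
S
  370.92285192  1.0
S
  114.65313506  1.0
S
  35.43955653  1.0
S
  10.95445115  1.0
S
  3.38604688  1.0
S
  1.04663514  1.0
S
  0.32351741  1.0
S
  0.10000000  1.0
P
  120.00000000  1.0
P
  38.93489827  1.0
P
  12.63271920  1.0
P
  4.09878031  1.0
P
  1.32987995  1.0
P
  0.43148951  1.0
P
  0.14000000  1.0
D
  26.00000000  1.0
D
  7.69994299  1.0
D
  2.28035085  1.0
D
  0.67532968  1.0
D
  0.20000000  1.0
F
  6.50000000  1.0
F
  1.50831031  1.0
F
  0.35000000  1.0
element O
S
  1600.00000000  1.0
S
  482.81312815  1.0
S
  145.69282295  1.0
S
  43.96400475  1.0
S
  13.26649916  1.0
S
  4.00327497  1.0
S
  1.20802107  1.0
S
  0.36453027  1.0
S
  0.11000000  1.0
P
  160.00000000  1.0
P
  50.05512252  1.0
P
  15.65947056  1.0
P
  4.89897949  1.0
P
  1.53261886  1.0
P
  0.47947141  1.0
P
  0.15000000  1.0
D
  34.00000000  1.0
D
  9.64305976  1.0
D
  2.73495887  1.0
D
  0.77568741  1.0
D
  0.22000000  1.0
F
  8.00000000  1.0
F
  1.78885438  1.0
F
  0.40000000  1.0
element S
S
  6000.00000000  1.0
S
  1975.87914011  1.0
S
  650.68306272  1.0
S
  214.27851507  1.0
S
  70.56474135  1.0
S
  23.23790008  1.0
S
  7.65254700  1.0
S
  2.52008467  1.0
S
  0.82989712  1.0
S
  0.27329607  1.0
S
  0.09000000  1.0
P
  600.00000000  1.0
P
  204.67105573  1.0
P
  69.81706842  1.0
P
  23.81588850  1.0
P
  8.12403840  1.0
P
  2.77125920  1.0
P
  0.94532758  1.0
P
  0.32246865  1.0
P
  0.11000000  1.0
D
  90.00000000  1.0
D
  31.32483232  1.0
D
  10.90272356  1.0
D
  3.79473319  1.0
D
  1.32077090  1.0
D
  0.45969919  1.0
D
  0.16000000  1.0
F
  12.00000000  1.0
F
  1.89736660  1.0
F
  0.30000000  1.0
G
  0.90000000  1.0
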