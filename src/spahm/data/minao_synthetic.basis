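# Synthetic minimal basis (registry key "MINAO"): STO-3G-style Slater-fit
# contractions generated in-package; NOT the literature MINAO data.
# Dialect: 'element <sym>' blocks; shell letter line; 'exponent coefficient' rows.
element H
S
  3.4251752336  0.1543068191
  0.6239045150  0.5352421072
  0.1688539544  0.4445551720
element C
S
  72.3750932223  0.1543068191
  13.1833101541  0.5352421072
  3.5679402819  0.4445551720
S
  6.8170142452  -0.0599426081
  0.4139497085  0.5960190246
  0.1589214133  0.4581618440
P
  2.4273943184  0.1623702976
  0.6229805015  0.5660930687
  0.2115101559  0.4222550624
element N
S
  99.9974741381  0.1543068191
  18.2147981785  0.5352421072
  4.9296657203  0.4445551720
S
  9.8165005131  -0.0599426081
  0.5960875802  0.5960190246
  0.2288468352  0.4581618440
P
  3.4954478186  0.1623702976
  0.8970919222  0.5660930687
  0.3045746245  0.4222550624
element O
S
  132.0750777823  0.1543068191
  24.0578165294  0.5352421072
  6.5110242940  0.4445551720
S
  13.3613479206  -0.0599426081
  0.8113414287  0.5960190246
  0.3114859701  0.4581618440
P
  4.7576928642  0.1623702976
  1.2210417830  0.5660930687
  0.4145599056  0.4222550624
element S
S
  549.0839251571  0.1543068191
  100.0170550906  0.5352421072
  27.0686857518  0.4445551720
S
  90.6283723403  -0.0599426081
  5.5032286809  0.5960190246
  2.1127708556  0.4581618440
S
  1.8625318090  -0.1782504637
  0.2286085464  0.8612452327
  0.1079424169  0.2261711332
P
  32.2708429521  0.1623702976
  8.2821755717  0.5660930687
  2.8119086265  0.4222550624
P
  8.8906602066  -0.0106187185
  0.4917101202  0.5218216988
  0.1894916773  0.5449642609
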