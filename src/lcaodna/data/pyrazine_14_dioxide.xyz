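12
pyrazine_14_dioxide MMFF94 geometry
O     -2.66263178     0.07998890     0.00202859
N     -1.40084869     0.04208326     0.00106830
C     -0.73080954    -1.16298098     0.02104029
C      0.65971088    -1.20475392     0.01998048
N      1.40084864    -0.04208326    -0.00106823
O      2.66263172    -0.07998895    -0.00203479
C      0.73080951     1.16298098    -0.02103816
C     -0.65971089     1.20475395    -0.01997771
H     -1.38050168    -2.02405509     0.03675757
H      1.25656583    -2.10327580     0.03474747
H      1.38050168     2.02405499    -0.03675835
H     -1.25656568     2.10327592    -0.03474547
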