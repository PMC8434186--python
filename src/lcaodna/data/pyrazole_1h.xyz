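9
pyrazole_1h MMFF94 geometry
C     -1.04650077    -0.62855755    -0.00632300
C     -0.70365328     0.73476664     0.04746218
C      0.67024261     0.74760575     0.01947063
N      1.05823843    -0.55914052    -0.04699231
N      0.02708971    -1.42028714    -0.06402560
H     -2.03157092    -1.07739277    -0.00589120
H     -1.36590373     1.58684359     0.09930487
H      1.39197247     1.55122599     0.04037480
H      2.00008548    -0.93506400    -0.08338037
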