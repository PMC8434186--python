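15
indazole_2h MMFF94 geometry
C     -0.81411703    -0.28170872    -1.89172234
C     -1.40915629     0.78716731    -1.14790830
C     -1.01426227     1.15502338     0.15537252
C      0.01895606     0.34401624     0.60696362
C      0.62936897     0.43547079     1.82557960
N      1.56878688    -0.55543398     1.81324560
N      1.60719927    -1.27728553     0.67618838
C      0.65051040    -0.74178102    -0.10131273
C      0.23742009    -1.08680845    -1.39829193
H     -1.19350139    -0.48496487    -2.89333887
H     -2.21616855     1.34904697    -1.62001707
H     -1.46931670     1.96351324     0.70930516
H      0.49627186     1.08552240     2.67751720
H      2.22264419    -0.79868257     2.54938874
H      0.68536451    -1.89309519    -1.96096957
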