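10
pyrimidine MMFF94 geometry
C     -1.14336457     0.10891773     0.04209996
C     -0.52408774    -1.11967415     0.03047217
N      0.81162490    -1.27899686    -0.01840825
C      1.53013871    -0.14576199    -0.05634707
N      1.03737093     1.10286063    -0.04967163
C     -0.30436872     1.19859393     0.00004270
H     -2.21833586     0.21131923     0.08167222
H     -1.10036642    -2.03971865     0.06100888
H      2.60888520    -0.24852481    -0.09608196
H     -0.69749644     2.21098494     0.00521298
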