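13
purine_7h MMFF94 geometry
C     -2.10619059    -0.78803624    -0.34978192
N     -2.18084018     0.46578369     0.15112973
C     -1.02796298     1.10910765     0.42748212
C      0.14917031     0.44123854     0.17912769
N      1.47548749     0.73754777     0.31932576
C      2.18673744    -0.35229244    -0.10558687
N      1.39760617    -1.32372281    -0.50743405
C      0.12707570    -0.84341140    -0.33570295
N     -1.00785994    -1.50686221    -0.61982350
H     -3.05541240    -1.27223229    -0.55910148
H     -1.09400731     2.11190776     0.82801196
H      1.86743376     1.59974983     0.67098234
H      3.26876254    -0.37877785    -0.09862882
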