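15
indazole_1h MMFF94 geometry
C     -1.81335547     0.83181080    -0.12993355
C     -1.90801543    -0.56065110    -0.15544662
C     -0.76690915    -1.36655518    -0.07737192
C      0.46496412    -0.71335719     0.02678909
N      1.74611568    -1.19025120     0.12003802
N      2.68669869    -0.23179839     0.20556730
C      1.97754561     0.89969740     0.16526898
C      0.58801441     0.67116999     0.05440360
C     -0.56857350     1.46545586    -0.02503062
H     -2.71699904     1.43400602    -0.19222938
H     -2.88707554    -1.02842167    -0.23755483
H     -0.84265675    -2.44856255    -0.09736786
H      2.04493333    -2.15829936     0.13061462
H      2.49824348     1.84675654     0.21805293
H     -0.50293045     2.54900001    -0.00579977
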