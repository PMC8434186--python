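15
aminopurine_2 MMFF94 geometry
N      3.00976308    -0.04618663     0.15124806
C      1.65587734     0.04055868    -0.10420264
N      1.30226591     0.22379533    -1.39077816
C     -0.01887827     0.30307188    -1.70338828
C     -0.96299048     0.17943226    -0.69434305
N     -2.33704699     0.20979151    -0.67449810
C     -2.65888174     0.03497553     0.59090443
N     -1.55270142    -0.10980329     1.38441756
C     -0.45709133    -0.02143215     0.57678672
N      0.82856504    -0.11009863     0.94309923
H      3.49410151    -0.32083887    -0.69215658
H      3.17104739    -0.59682792     0.98191861
H     -0.27700876     0.46091536    -2.74186805
H     -3.66454920     0.00450288     0.98998975
H     -1.53247209    -0.25185595     2.38287051
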