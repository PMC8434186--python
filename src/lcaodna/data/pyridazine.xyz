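10
pyridazine MMFF94 geometry
C     -0.72069457     0.77191903     0.01212448
C      0.66527300     0.82023916    -0.00511919
C      1.35595849    -0.37615556    -0.01856188
N      0.73578783    -1.57384593    -0.01551132
N     -0.62456796    -1.62127301     0.00143049
C     -1.32651481    -0.46967672     0.01483393
H     -1.31439619     1.67847518     0.02318348
H      1.19449601     1.76594640    -0.00801112
H      2.43900638    -0.41338665    -0.03233430
H     -2.40434818    -0.58224190     0.02796542
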