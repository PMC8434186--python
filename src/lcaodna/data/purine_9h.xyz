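13
purine_9h MMFF94 geometry
C     -1.91662099    -1.03877757     0.13586602
N     -2.22181523     0.04762320    -0.61008717
C     -1.22391903     0.92772429    -0.88887432
C      0.05609824     0.68314993    -0.40426628
N      1.24809032     1.36157689    -0.50863370
C      2.11196809     0.63064775     0.16546346
N      1.52974556    -0.48748479     0.69887697
C      0.21250591    -0.47147273     0.34463807
N     -0.72080586    -1.38228400     0.65913153
H     -2.73849809    -1.71971638     0.33854107
H     -1.47445421     1.79451136    -1.48585754
H      3.16173659     0.85639709     0.30153331
H      1.97596870    -1.20189504     1.25366858
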