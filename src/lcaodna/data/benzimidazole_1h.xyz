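15
benzimidazole_1h MMFF94 geometry
C     -2.01826160    -0.58382937    -0.16087805
C     -1.85999352     0.80384384    -0.11360144
C     -0.59268641     1.38946616    -0.00692841
C      0.49656306     0.51743674     0.04923961
N      1.84786558     0.72808883     0.15229880
C      2.46544338    -0.49075971     0.16542947
N      1.60060669    -1.47494241     0.07753702
C      0.37019537    -0.86747683     0.00434085
C     -0.90733506    -1.43530500    -0.10261913
H     -3.01462780    -1.01145214    -0.24390266
H     -2.73998450     1.44244206    -0.16067658
H     -0.47175338     2.46635581     0.02961548
H      2.30608519     1.62550711     0.20857682
H      3.53940676    -0.59662525     0.24027262
H     -1.02152375    -2.51274983    -0.13870440
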