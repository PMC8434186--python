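9
imidazole_1h MMFF94 geometry
C     -1.05828617    -0.63571556    -0.01903293
C     -0.72243726     0.69632385     0.03309467
N      0.64481990     0.71752347     0.02505954
C      1.07493004    -0.57775393    -0.03055286
N      0.06657823    -1.41836102    -0.05826420
H     -2.04822852    -1.07324296    -0.03043274
H     -1.31642562     1.59783317     0.07371846
H      1.23559692     1.53695277     0.05462533
H      2.12345248    -0.84355978    -0.04821527
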