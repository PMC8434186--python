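10
pyrazine MMFF94 geometry
C      1.15194220    -0.37902975    -0.55948143
C      1.13156693     0.41185728     0.57756275
N     -0.02085355     0.80945111     1.16386483
C     -1.15194039     0.37896680     0.55952464
C     -1.13156558    -0.41192206    -0.57751761
N      0.02085512    -0.80958104    -1.16377483
H      2.08397992    -0.68922889    -1.01749664
H      2.04693108     0.74885899     1.05003860
H     -2.08398185     0.68936099     1.01739996
H     -2.04693388    -0.74873343    -1.05012028
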