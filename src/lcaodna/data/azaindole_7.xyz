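15
azaindole_7 MMFF94 geometry
C     -1.98153226    -0.99265864    -0.02132291
C     -2.16577443     0.37574314    -0.18025447
C     -1.04911456     1.21309414    -0.19808827
C      0.21228587     0.61487955    -0.05236041
C      1.55837486     1.06988246    -0.01430752
C      2.36852431    -0.03405873     0.15662549
N      1.56009808    -1.14091202     0.22333040
C      0.25034051    -0.76720480     0.09858465
N     -0.79100002    -1.61932888     0.12289230
H     -2.84225202    -1.65760621    -0.00544925
H     -3.16428939     0.78507058    -0.28873337
H     -1.15397847     2.28555268    -0.32005977
H      1.89819823     2.09341682    -0.10232327
H      3.44317303    -0.12820055     0.23615410
H      1.85694626    -2.09766955     0.34531230
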