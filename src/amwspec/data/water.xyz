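3
water monomer, ground-state effective geometry: r(OH) = 0.9572 A, HOH = 104.52 deg
O    0.00000000   0.00000000   0.00000000   15.994915 O
H    0.95720000   0.00000000   0.00000000    1.007825 H1
H    -0.23998721    0.92662721   0.00000000    1.007825 H2
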