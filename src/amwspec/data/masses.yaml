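# Atomic isotope masses in u (AME2020 atomic mass evaluation, rounded to
# six decimals).  Plain element symbols map to the most abundant isotope.
masses:
  H: 1.007825
  H1: 1.007825
  D: 2.014102
  H2: 2.014102
  C: 12.0
  C12: 12.0
  C13: 13.003355
  N: 14.003074
  N14: 14.003074
  N15: 15.000109
  O: 15.994915
  O16: 15.994915
  O18: 17.999160
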