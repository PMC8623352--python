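13
synthetic stand-in geometry for 2-aminopyridine: experimental pyridine ring + standard amino substitution, axis-scaled and H5/H6-refined to ground-state monomer isotopologue moments
N      0.28370376   -1.19076428    0.00789668   14.003074 Nr
C      0.88983165    0.00218960    0.01325447   12.000000 C2
C      0.20375537    1.21631110    0.00785129   12.000000 C3
C     -1.19299501    1.19605948   -0.00379142   12.000000 C4
C     -1.83942784   -0.03695777   -0.00949536   12.000000 C5
C     -1.05898701   -1.19319696   -0.00329102   12.000000 C6
H      0.74547755    2.15434067    0.01260672    1.007825 H3
H     -1.76256059    2.11666212   -0.00829954    1.007825 H4
H     -2.91513535   -0.17292860   -0.01854972    1.007825 H5
H     -1.47061070   -2.19620776   -0.00780230    1.007825 H6
N      2.26973082    0.03251203    0.02475938   14.003074 Na
H      2.82747448   -0.76453406   -0.24286092    1.007825 H_Na1
H      2.79160309    0.85331735   -0.24274259    1.007825 H_Na2
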