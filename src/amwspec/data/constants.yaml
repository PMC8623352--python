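# Experimental spectroscopic constants of 2-aminopyridine (AMP) and of
# its 1:1 water cluster (AMW), as determined from supersonic-expansion
# FTMW + room-temperature MMW rotational spectroscopy.
# Units: A, B, C in MHz; quartic distortion constants in kHz; HK in Hz;
# hyperfine parameters in MHz; dipole components in D.
# chi32aa = (3/2) chi_aa and chibbcc4 = (chi_bb - chi_cc)/4 are the
# combinations varied directly in the fits.

amp:
  dipoles: {mu_a: 0.166, mu_b: 0.86, mu_c: 0.0}
  0plus:
    A: 5780.37487
    B: 2733.50446
    C: 1857.675172
    DJ: 0.137392
    DJK: 0.202586
    DK: 0.93717
    dJ: 0.0458083
    dK: 0.365545
    HK: 0.000643
  0minus:
    A: 5778.56502
    B: 2730.18938
    C: 1857.14913
    DJ: 0.137264
    DJK: 0.203231
    DK: 0.93003
    dJ: 0.0456266
    dK: 0.364984
    HK: 0.000571
  parent:
    A: 5780.374597
    B: 2733.504446
    C: 1857.675169
    DJ: 0.137393
    DJK: 0.202569
    DK: 0.93701
    dJ: 0.0458083
    dK: 0.365563
    HK: 0.000605
    hyperfine:
      Na: {chi32aa: 3.5854, chibbcc4: 1.50413}
      Nr: {chi32aa: -0.0789, chibbcc4: -1.15823}
  d5:
    A: 5778.43386
    B: 2613.82591
    C: 1801.46262
    hyperfine:
      Na: {chi32aa: 3.6005, chibbcc4: 1.5056}
      Nr: {chi32aa: -0.048, chibbcc4: -1.1695}
  d6:
    A: 5485.85599
    B: 2700.45410
    C: 1811.36749
    hyperfine:
      Na: {chi32aa: 3.5732, chibbcc4: 1.5021}
      Nr: {chi32aa: 0.226, chibbcc4: -1.2171}

amw:
  dipoles: {mu_a: 1.0, mu_b: 0.4, mu_c: 0.0}   # nominal relative values; a-type dominant
  parent:
    A: 3722.8201
    B: 1384.23544
    C: 1011.15836
    DJ: 0.2058
    DJK: 0.419
    DK: 2.21
    dJ: 0.0588
    dK: 0.612
    hyperfine:
      Na: {chi32aa: 3.0091, chibbcc4: 1.55556}
      Nr: {chi32aa: -4.8756, chibbcc4: -0.1284, chiab: 1.43}
  d5:
    A: 3640.3373
    B: 1354.60499
    C: 989.28824
    DJ: 0.2533
    hyperfine:
      Na: {chi32aa: 3.113, chibbcc4: 1.542}
      Nr: {chi32aa: -4.821, chibbcc4: -0.1455}
  d6:
    A: 3558.6210
    B: 1383.47362
    C: 998.26318
    DJ: 0.2279
    hyperfine:
      Na: {chi32aa: 2.975, chibbcc4: 1.5513}
      Nr: {chi32aa: -4.816, chibbcc4: -0.1256}

# Full quadrupole tensors in inertial axes (MHz) and their principal-axis
# summaries.  "calc" values are quantum-chemistry tensors scaled by the
# factor below, which reproduces chi_cc of both nitrogen nuclei in the
# AMP monomer.
tensors:
  scaling_factor: 0.941
  amp:
    exp:
      Na: {chi_aa: 2.3903, chi_bb: 1.8132, chi_cc: -4.2034, chi_ab: 0.0}
      Nr: {chi_aa: -0.0526, chi_bb: -2.2903, chi_cc: 2.3428, chi_ab: 2.92}
    calc:
      Na: {chi_aa: 2.300, chi_bb: 1.903, chi_cc: -4.203, chi_ab: 0.0}
      Nr: {chi_aa: -0.035, chi_bb: -2.309, chi_cc: 2.343, chi_ab: 2.92}
    principal:
      Nr: {chi_zz_exp: -4.30, theta_za_exp: 55.5, chi_zz_calc: -4.310, theta_za_calc: 55.6}
  amw:
    exp:
      Na: {chi_aa: 2.0061, chi_bb: 2.1081, chi_cc: -4.1142, chi_ab: 0.0}
      Nr: {chi_aa: -3.2504, chi_bb: 1.3684, chi_cc: 1.8820, chi_ab: 1.43}
    calc:
      Na: {chi_aa: 1.991, chi_bb: 2.087, chi_cc: -4.078, chi_ab: 0.0}
      Nr: {chi_aa: -3.249, chi_bb: 1.481, chi_cc: 1.769, chi_ab: 1.715}
    principal:
      Nr: {chi_zz_exp: -3.66, theta_za_exp: 15.9, chi_zz_calc: -3.829,
           theta_za_calc: 18.3, theta_str_exp: 17.5, theta_str_calc: 19.9}

# Experimental ground-state moments of inertia (u A^2) of the AMW cluster
# isotopologues, the inputs of the three-parameter r0 structure fit, and
# the published fit results for comparison.
structure:
  moments:
    parent: [135.7523, 365.0978, 499.8001]
    d5: [138.8246, 373.0822, 510.8523]
    d6: [142.0154, 365.2971, 506.2585]
  fitted:
    d_O_Nr: 2.8489
    angle_O_Nr_C2: 102.71
    dihedral_HOH_Nr: 140.9
    sigma_fit: 0.0247
  computed:
    d_O_Nr: 2.8272
    angle_O_Nr_C2: 101.75
    dihedral_HOH_Nr: 134.3
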