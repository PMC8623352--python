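# Methods

## Rotational Hamiltonian

Energy levels come from the Watson A-reduced effective rotational
Hamiltonian in representation Iʳ (inertial a axis taken as the
quantization axis z, x = b, y = c):

    H = (B+C)/2 · J² + [A − (B+C)/2] · Jz²  +  (B−C)/4 · (J₊² + J₋²)
        − Δ_J J⁴ − Δ_JK J²Jz² − Δ_K Jz⁴
        − 2δ_J J²(Jx²−Jy²) − δ_K [Jz²(Jx²−Jy²) + (Jx²−Jy²)Jz²]
        + H_K Jz⁶

Internally everything is in MHz; quartic constants are accepted in kHz
and H_K in Hz at the I/O boundary, matching how tables quote them.  Only
the A reduction in Iʳ is supported — other reductions are rejected
rather than silently approximated.  The matrix is built in the signed-k
basis, block-diagonalized by the Wang transform (E±/O± blocks), and each
block is diagonalized with `numpy.linalg.eigh`.  (K_a, K_c) labels are
assigned by sorting each J block by energy onto the standard ladder,
with exact degeneracies broken by Wang-block order.  Energies are
referenced to the 0₀₀ level of each vibronic state; the 0⁺ and 0⁻
inversion sublevels of the monomer are carried as independent
constant sets with no inversion-coupling term, adequate because their
rotational ladders are far apart compared to any coupling.

The moment/frequency conversion constant is fixed at
505379.07 MHz·uÅ² (configurable argument for sensitivity checks).  The
published cluster moments differ from moments recomputed from the
published rotational constants by up to ~0.002 uÅ² (the
conversion-constant convention of the original tabulation is not
recoverable), so tests compare moments at 0.003 uÅ².

## Hyperfine treatment

Each ¹⁴N nucleus (I = 1) carries a traceless quadrupole tensor with an
in-plane off-diagonal element χ_ab only.  The interaction is treated
first order within each rotational level: the level-projected coupling
constant is χ_eff = 2 Σ_g χ_gg ⟨J_g²⟩ / J(J+1), with ⟨J_g²⟩ from the
rotor eigenvectors.  For two nuclei the interaction matrix is built in
the coupled basis |(J, I_tot) F⟩ via 6-j recoupling, normalized against
the closed-form single-nucleus (Casimir) energy through the stretched
state, and diagonalized per F block.  The off-diagonal χ_ab does not
contribute within a level at first order; it enters the analysis through
the tensor-geometry operations (rotation, diagonalization) instead,
exactly as it is used in practice.  Couplings are of order MHz against
GHz rotational spacings, so neglected level mixing contributes at the
sub-kHz level, below the 2 kHz measurement accuracy modelled.

Sublevels within an F block are labelled by their dominant I_tot
contribution, resolved as an optimal assignment so that strongly mixed
near-degenerate states still get unique labels; measured components are
matched to predicted ones first by exact (I_tot, F) labels and otherwise
by maximal I_tot-composition overlap.  Fits started far from the truth
(≳0.1 MHz on a hyperfine combination here) can re-assign components and
converge to a wrong minimum — the usual requirement of adequate starting
constants in hyperfine analysis applies.

Relative component intensities use the standard coupled-basis
line-strength factors with coherent summation over the spectator I_tot,
normalized within each rotational transition; the intensity-weighted
mean offset of a pattern vanishes (center-of-gravity rule), which the
tests assert.

Tensor conventions: rotation by θ turns a toward b
(χ'_aa = χ_aa cos²θ + χ_bb sin²θ + 2χ_ab sinθ cosθ); χ_zz is the
largest-magnitude eigenvalue (for both nitrogen nuclei here it lies in
the ab plane); θ_za is reported as a magnitude in [0°, 90°] with the
signed value retained for the bond-angle correction
θ_str = θ_za(exp) + [θ_str(calc) − θ_za(calc)].  If the out-of-plane
component is the largest eigenvalue, θ_za is 90° by convention.

## Spectrum prediction and fitting

Line strengths are computed from molecule-frame dipole matrix elements
contracted with the rotor eigenvectors (rank-1 Clebsch–Gordan factors in
closed form); a/b/c-type selection rules emerge from the matrix elements
and are used as branch labels.  Intensities are ν·S·(e^{−E″/kT} −
e^{−E′/kT}) with a 1 K default for jet conditions and 300 K for
room-temperature runs; absolute calibration is out of scope.

Type-II bands — clumps of a-type R-branch transitions with decreasing J
and increasing K_a at nearly constant frequency, characteristic of
near-planar tops at high J — are detected on a smoothed binned intensity
profile (25 MHz bins, 150 MHz Gaussian smoothing, peaks above 25 %
prominence); the mean center spacing estimates 2C.  Fewer than two
detected bands is an error, not a guess.

`fit_constants` minimizes Σ[(obs−calc)/u]² over a line list with the
MINPACK Levenberg–Marquardt implementation (finite-difference Jacobian,
relative tolerance 1e-10, iteration cap configurable).  Hyperfine-
resolved lines are matched to specific components; blended lines to the
intensity-weighted centroid of their listed components.  Standard errors
come from the unscaled weighted covariance (JᵀWJ)⁻¹, so they track the
supplied measurement uncertainties (doubling all uncertainties doubles
the errors and leaves values unchanged).  σ_fit is reported per source
tag as the plain rms of (obs−calc) in kHz, alongside the unitless
weighted deviation.  Fixed-parameter strategies (deuterated species
inheriting parent distortion constants) are expressed through the free-
parameter mask.

## Structure determination

The cluster model is rigid: a planar (within tolerance) aromatic partner
in its principal frame plus a rigid water.  The three fitted parameters
are d(O···N_r), ∠(O···N_r–C2) (oxygen placed exactly in the molecular
plane, on the amino side), and the dihedral D(HOH···N_r), implemented as
the IUPAC signed dihedral H2–O–N_r–C2 — well-defined even when the
donated hydrogen lies exactly on the O···N_r line.  The O–H···N_r
nonlinearity is a frozen assumption, default 0°, settable in config; the
donated hydrogen stays in the molecular plane.  Only magnitudes of the
dihedral are compared externally since its sign convention is not fixed
by the data.

`r0_fit` adjusts the three parameters against the 3×3 isotopologue
moments with the same least-squares machinery; σ_fit is the rms of the
nine residuals, with the dof-corrected value sqrt(SSR/(N−p)) — the
convention structure-fit programs print — reported alongside.  Standard
errors are statistical (scaled by the residual variance) and, as always
for r₀ fits, optimistic relative to the model error of the frozen
monomer geometries.

### The monomer stand-in

The original scaled monomer geometry is not published, so the package
ships a synthetic stand-in (`data/amp_synthetic.xyz`, regenerable with
`scripts/make_amp_fixture.py`): the experimental r₀ pyridine ring with a
standard amino substitution (r(C–N) 1.375 Å, slightly pyramidal NH₂),
refined against the nine experimental ground-state moments of the
parent, 5-d and 6-d monomer isotopologues — one scale factor per
principal axis (the planar-moment scaling trick, generalized) plus
in-plane shifts of the two ring hydrogens that the deuterium data pin
directly.  The refined fixture reproduces all nine monomer moments to
0.0007 uÅ² with C–H bond lengths of 1.084 Å.  The water monomer is the
effective ground-state geometry r(OH) = 0.9572 Å, ∠HOH = 104.52°.

With this stand-in the r₀ fit to the nine experimental cluster moments
gives d(O···N_r) = 2.863 Å (published: 2.8489 Å) with σ_fit =
0.034 uÅ²; the ~0.014 Å difference is monomer-geometry model error, of
the same order as the realistic uncertainty the original analysis
assigns to its own result.  Tests therefore compare the distance at
0.02 Å, never exactly.

## Synthetic data

Generators are pure functions of (inputs, seed), using
`numpy.random.default_rng`.  Defaults mirror the stated measurement
conditions: 2 kHz (FTMW) and 50 kHz (MMW) Gaussian frequency noise, and
0.025 uÅ² moment-level noise for structure-fit calibration.  The
generators emulate assigned, resolved center frequencies only — no
lineshapes, Doppler doubling, intensity noise, unresolved deuterium
splitting, or mis-assignments — so passing recovery tests demonstrate
correctness and statistical calibration of the estimators, not
robustness to the pathologies of real spectra.

Problem sizes used by the test suite and self-checks: line lists of
40–100 lines at J ≤ 9, 50-seed fit-recovery calibration, 25-seed
structure-scatter calibration, rotor-oracle equivalence at J ≤ 10 and
band detection at J ≤ 95 — all chosen as the smallest sets that make the
statistical assertions sharp.

## Known limitations

* S-reduction, vibration–rotation interaction, inversion-tunneling
  coupling and sextic constants beyond H_K are out of scope.
* Hyperfine is first order per rotational level; deuterium quadrupole
  coupling is not modelled (deuterated species are fitted with the same
  two-spin model, as in the original analysis, at the cost of larger
  residuals on real data).
* Kraitchman substitution coordinates and r_m / semi-experimental
  structures are deliberately not implemented.
* The r₀ parameters inherit the frozen-monomer model error; standard
  errors quantify only the statistical component.
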