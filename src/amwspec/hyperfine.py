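"""Nuclear quadrupole coupling for one or two I=1 nuclei.

Covers the tensor-level operations used in the analysis of in-plane
nitrogen nuclei (parameterization used in fits, in-plane rotation,
diagonalization to principal quadrupolar axes, uniform scaling) and the
prediction of hyperfine splitting patterns of rotational transitions in
the coupled scheme I_tot = I(1) + I(2), F = J + I_tot.

The hyperfine interaction is treated first order within each rotational
level: the quadrupole Hamiltonian of each nucleus is projected onto the
level via the field-gradient expectation values <Jg^2> and the resulting
matrix in the |(J, I_tot) F> basis is diagonalized per F block (6-j
recoupling).  Couplings of a few MHz against rotational spacings of GHz
make level mixing negligible at the kHz accuracies modelled here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Sequence

import numpy as np

from .rotor import AsymmetricRotor, InvalidInputError, RotationalLevel

__all__ = [
    "QuadrupoleTensor",
    "HyperfineFitParams",
    "PrincipalTensor",
    "HyperfineComponent",
    "tensor_from_fit_params",
    "fit_params_from_tensor",
    "rotate_tensor",
    "diagonalize_tensor",
    "theta_str_correction",
    "scale_tensor",
    "chi_eff",
    "quadrupole_sublevels",
    "hyperfine_pattern",
]

_LAPLACE_TOL = 1e-6


@dataclass(frozen=True)
class QuadrupoleTensor:
    """Traceless coupling tensor of one nucleus in inertial axes (MHz).

    Only the in-plane off-diagonal element chi_ab is carried; chi_ac and
    chi_bc vanish for a nucleus in the ab inertial plane of a planar
    molecule.
    """

    chi_aa: float
    chi_bb: float
    chi_cc: float
    chi_ab: float = 0.0
    nucleus_label: str = "N"
    spin: float = 1.0

    def __post_init__(self):
        if abs(self.chi_aa + self.chi_bb + self.chi_cc) > _LAPLACE_TOL:
            raise InvalidInputError(
                "tensor violates the Laplace relation chi_aa+chi_bb+chi_cc=0")

    @property
    def is_zero(self) -> bool:
        return (self.chi_aa == 0 and self.chi_bb == 0
                and self.chi_cc == 0 and self.chi_ab == 0)

    def diagonal(self) -> tuple[float, float, float]:
        return (self.chi_aa, self.chi_bb, self.chi_cc)


@dataclass(frozen=True)
class HyperfineFitParams:
    """The two linear combinations used as direct fit parameters (MHz).

    three_halves_chi_aa = (3/2) chi_aa and quarter_chi_bb_minus_cc =
    (chi_bb - chi_cc)/4; together with the traceless condition they fix
    the diagonal tensor.  chi_ab is optional and usually held fixed.
    """

    three_halves_chi_aa: float
    quarter_chi_bb_minus_cc: float
    chi_ab: float = 0.0
    nucleus_label: str = "N"


@dataclass(frozen=True)
class PrincipalTensor:
    """Eigenvalues of a quadrupole tensor and the z-to-a axis angle.

    chi_zz is the largest-magnitude eigenvalue.  theta_za is the angle
    between its eigenvector and the inertial a axis, reported as a
    magnitude in [0, 90] degrees; the signed value is kept for angle
    bookkeeping.  When the z axis is the out-of-plane c axis theta_za is
    90 degrees by convention.
    """

    chi_zz: float
    chi_xx: float
    chi_yy: float
    theta_za: float
    theta_za_signed: float
    degenerate: bool = False


@dataclass(frozen=True)
class HyperfineComponent:
    """One F-resolved component of a rotational transition.

    The I_tot entries of the labels are the dominant coupled-spin
    contributions; upper_weights / lower_weights give the full |c|^2
    composition over I_tot, which line matching uses when near-degenerate
    sublevels mix strongly.
    """

    upper: tuple  # (J, Ka, Kc, I_tot, F)
    lower: tuple
    offset: float  # MHz, relative to the unsplit rotational frequency
    intensity: float  # relative, sums to 1 within the rotational transition
    upper_weights: tuple = ()   # ((I_tot, |c|^2), ...)
    lower_weights: tuple = ()


def tensor_from_fit_params(p: HyperfineFitParams) -> QuadrupoleTensor:
    """Diagonal tensor from the fitted combinations via the traceless condition."""
    chi_aa = (2.0 / 3.0) * p.three_halves_chi_aa
    diff = 4.0 * p.quarter_chi_bb_minus_cc        # chi_bb - chi_cc
    chi_bb = 0.5 * (diff - chi_aa)
    chi_cc = -chi_aa - chi_bb
    return QuadrupoleTensor(chi_aa=chi_aa, chi_bb=chi_bb, chi_cc=chi_cc,
                            chi_ab=p.chi_ab, nucleus_label=p.nucleus_label)


def fit_params_from_tensor(t: QuadrupoleTensor) -> HyperfineFitParams:
    return HyperfineFitParams(
        three_halves_chi_aa=1.5 * t.chi_aa,
        quarter_chi_bb_minus_cc=0.25 * (t.chi_bb - t.chi_cc),
        chi_ab=t.chi_ab,
        nucleus_label=t.nucleus_label,
    )


def rotate_tensor(t: QuadrupoleTensor, theta_deg: float) -> QuadrupoleTensor:
    """Rotate the ab block by theta (degrees); positive theta turns a toward b.

    chi'_aa = chi_aa cos^2 + chi_bb sin^2 + 2 chi_ab sin cos, the similarity
    transform of the 2x2 in-plane block; chi_cc, the trace and the
    eigenvalues are unchanged.
    """
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    aa = t.chi_aa * c * c + t.chi_bb * s * s + 2.0 * t.chi_ab * s * c
    bb = t.chi_aa * s * s + t.chi_bb * c * c - 2.0 * t.chi_ab * s * c
    ab = (t.chi_bb - t.chi_aa) * s * c + t.chi_ab * (c * c - s * s)
    return replace(t, chi_aa=aa, chi_bb=bb, chi_cc=t.chi_cc, chi_ab=ab)


def diagonalize_tensor(t: QuadrupoleTensor) -> PrincipalTensor:
    """Diagonalize the in-plane block; z = largest-magnitude eigenvalue.

    For an in-plane nucleus the c axis is already principal, so the
    operation reduces to a rotation in the ab plane by theta_za.
    """
    half_sum = 0.5 * (t.chi_aa + t.chi_bb)
    half_diff = 0.5 * (t.chi_aa - t.chi_bb)
    degenerate = (half_diff == 0.0 and t.chi_ab == 0.0)
    r = math.hypot(half_diff, t.chi_ab)
    lam_hi = half_sum + r   # eigenvector closer to +a when chi_aa > chi_bb
    lam_lo = half_sum - r
    # angle of the eigenvector of lam_hi with respect to the a axis
    if degenerate:
        ang_hi = 0.0
    else:
        ang_hi = 0.5 * math.atan2(2.0 * t.chi_ab, t.chi_aa - t.chi_bb)
    ang_lo = ang_hi + 0.5 * math.pi

    cands = [(lam_hi, ang_hi), (lam_lo, ang_lo)]
    cands.sort(key=lambda p: abs(p[0]), reverse=True)
    in_plane_z, in_plane_x = cands
    if abs(t.chi_cc) > abs(in_plane_z[0]):
        # principal z is the out-of-plane axis
        chi_zz = t.chi_cc
        chi_xx, chi_yy = in_plane_x[0], in_plane_z[0]
        signed = 0.5 * math.pi
    else:
        chi_zz = in_plane_z[0]
        chi_xx, chi_yy = in_plane_x[0], t.chi_cc
        signed = math.atan2(math.sin(in_plane_z[1]), math.cos(in_plane_z[1]))
        # fold to (-90, 90]: eigenvector direction is defined modulo 180 deg
        if signed > 0.5 * math.pi:
            signed -= math.pi
        elif signed <= -0.5 * math.pi:
            signed += math.pi
    signed_deg = math.degrees(signed)
    return PrincipalTensor(chi_zz=chi_zz, chi_xx=chi_xx, chi_yy=chi_yy,
                           theta_za=abs(signed_deg), theta_za_signed=signed_deg,
                           degenerate=degenerate)


def theta_str_correction(theta_za_exp: float, theta_za_calc: float,
                         theta_str_calc: float) -> float:
    """Bond-axis angle from the experimental theta_za.

    The small, calculable difference between the principal quadrupolar z
    axis and the structural axis is transferred from computation:
    theta_str = theta_za_exp + (theta_str_calc - theta_za_calc).
    """
    return theta_za_exp + (theta_str_calc - theta_za_calc)


def scale_tensor(t: QuadrupoleTensor, factor: float) -> QuadrupoleTensor:
    """Multiply all components by a positive scaling factor."""
    if factor <= 0:
        raise InvalidInputError("scaling factor must be positive")
    return replace(t, chi_aa=t.chi_aa * factor, chi_bb=t.chi_bb * factor,
                   chi_cc=t.chi_cc * factor, chi_ab=t.chi_ab * factor)


# --------------------------------------------------------------------------
# Hyperfine energies in the coupled basis |(J, I_tot) F>
# --------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _sixj(a, b, c, d, e, f) -> float:
    from sympy.physics.wigner import wigner_6j
    return float(wigner_6j(a, b, c, d, e, f))


def _stretched_3j(j: float) -> float:
    """(j 2 j; -j 0 j) Wigner 3-j symbol, closed form."""
    tj = 2 * j
    return 2.0 * j * (tj - 1) / math.sqrt((tj + 3) * (tj + 2) * (tj + 1) * tj * (tj - 1))


def chi_eff(t: QuadrupoleTensor, jg2: tuple[float, float, float], J: int) -> float:
    """Level-projected coupling constant 2 sum_g chi_gg <Jg^2> / (J(J+1)).

    Reduces to eQq (3K^2/(J(J+1)) - 1) in the symmetric-top limit; zero
    for J = 0 where the field gradient averages out.
    """
    if J == 0:
        return 0.0
    ja2, jb2, jc2 = jg2
    return 2.0 * (t.chi_aa * ja2 + t.chi_bb * jb2 + t.chi_cc * jc2) / (J * (J + 1))


def _reduced_product(chi: float, J: int, I: float) -> float:
    """<J||V2||J><I||Q2||I> product calibrated against the first-order
    single-nucleus energy: the stretched state F = J+I must have energy
    chi_eff * J / (4(2J+3))."""
    if J == 0:
        return 0.0
    y_stretch = J / (4.0 * (2 * J + 3))
    return chi * y_stretch / (_stretched_3j(J) * _stretched_3j(I))


def _itot_values(I1: float, I2: float) -> list[float]:
    lo, hi = abs(I1 - I2), I1 + I2
    return [lo + k for k in range(int(round(hi - lo)) + 1)]


def quadrupole_sublevels(J: int, chis: Sequence[float], spins: Sequence[float]):
    """F-resolved hyperfine sublevels of one rotational level.

    chis are the level-projected coupling constants (chi_eff) of each
    nucleus.  Returns a list of (F, shifts, vectors, itots): per F block
    the eigenvalues (MHz), eigenvectors in the I_tot basis and the list
    of I_tot values spanning the block.
    """
    if len(chis) == 1:
        # single nucleus: |(J, I) F> basis, diagonal in F
        I = spins[0]
        p = _reduced_product(chis[0], J, I) if I >= 1 else 0.0
        out = []
        F = abs(J - I)
        while F <= J + I + 1e-9:
            shift = ((-1.0) ** (J + I + F)) * _sixj(J, I, F, I, J, 2) * p
            out.append((F, np.array([shift]), np.eye(1), [I]))
            F += 1.0
        return out
    if len(chis) != 2 or len(spins) != 2:
        raise InvalidInputError("expected one or two nuclei")
    I1, I2 = spins
    ps = [_reduced_product(chis[0], J, I1) if I1 >= 1 else 0.0,
          _reduced_product(chis[1], J, I2) if I2 >= 1 else 0.0]
    itots_all = _itot_values(I1, I2)
    out = []
    fmin = min(abs(J - it) for it in itots_all)
    fmax = J + max(itots_all)
    F = fmin
    while F <= fmax + 1e-9:
        itots = [it for it in itots_all if abs(J - it) <= F <= J + it]
        if itots:
            n = len(itots)
            M = np.zeros((n, n))
            for a, itb in enumerate(itots):       # bra
                for b, itk in enumerate(itots):   # ket
                    M[a, b] = (_coupled_element(J, I1, I2, itb, itk, F, 1) * ps[0]
                               + _coupled_element(J, I1, I2, itb, itk, F, 2) * ps[1])
            w, v = np.linalg.eigh(M)
            out.append((F, w, v, itots))
        F += 1.0
    return out


def _coupled_element(J: int, I1: float, I2: float, it_bra: float,
                     it_ket: float, F: float, nucleus: int) -> float:
    """Recoupling factor of T2(V).T2(Q_n) between I_tot states at fixed F,
    with the reduced matrix element product divided out."""
    if J == 0:
        return 0.0
    # scalar product of rank-2 tensors acting on the rotational and total
    # spin parts of |(J, I_tot) F>
    scalar = ((-1.0) ** (J + it_bra + F)) * _sixj(J, it_bra, F, it_ket, J, 2)
    if scalar == 0.0:
        return 0.0
    # reduced matrix element of Q_n within the coupled spin pair
    pre = math.sqrt((2 * it_bra + 1) * (2 * it_ket + 1))
    if nucleus == 1:
        spin = ((-1.0) ** (I1 + I2 + it_ket)) * pre * _sixj(I1, it_bra, I2, it_ket, I1, 2)
    else:
        spin = ((-1.0) ** (I1 + I2 + it_bra)) * pre * _sixj(I2, it_bra, I1, it_ket, I2, 2)
    return scalar * spin


def _assign_itot_labels(vectors: np.ndarray, itots: list[float]) -> list[float]:
    """Unique I_tot label per eigenstate of one F block.

    Labels follow the dominant coupled-basis contribution, resolved as an
    optimal assignment so that strongly mixed near-degenerate states
    still receive distinct labels.
    """
    from scipy.optimize import linear_sum_assignment
    w = vectors**2  # rows: I_tot basis, cols: eigenstates
    rows, cols = linear_sum_assignment(-w.T)
    out = [None] * vectors.shape[1]
    for state, basis in zip(rows, cols):
        out[state] = itots[basis]
    return out


def hyperfine_pattern(upper: RotationalLevel, lower: RotationalLevel,
                      tensors: Sequence[QuadrupoleTensor],
                      rotor_upper: AsymmetricRotor,
                      rotor_lower: AsymmetricRotor | None = None
                      ) -> list[HyperfineComponent]:
    """F-resolved components of the transition upper <- lower.

    Shifts come from per-F diagonalization of the projected quadrupole
    interaction in each rotational level; relative intensities from the
    coupled-basis line-strength factors with coherent summation over the
    spectator I_tot, normalized to 1 within the rotational transition.
    """
    if rotor_lower is None:
        rotor_lower = rotor_upper
    tensors = list(tensors)
    if not 1 <= len(tensors) <= 2:
        raise InvalidInputError("expected one or two quadrupole tensors")
    spins = [t.spin for t in tensors]

    def sublevels(level: RotationalLevel, rotor: AsymmetricRotor):
        jg2 = rotor.jg_squared(level.J, level.Ka, level.Kc)
        chis = [chi_eff(t, jg2, level.J) for t in tensors]
        return quadrupole_sublevels(level.J, chis, spins)

    up = sublevels(upper, rotor_upper)
    lo = sublevels(lower, rotor_lower)

    comps = []
    up = [(F, w, v, it, _assign_itot_labels(v, it)) for F, w, v, it in up]
    lo = [(F, w, v, it, _assign_itot_labels(v, it)) for F, w, v, it in lo]
    for Fu, wu, vu, itu, labu in up:
        for Fl, wl, vl, itl, labl in lo:
            if abs(Fu - Fl) > 1 or (Fu == 0 and Fl == 0):
                continue
            common = [it for it in itu if it in itl]
            if not common:
                continue
            for iu in range(len(wu)):
                for il in range(len(wl)):
                    amp = 0.0
                    for it in common:
                        cu = vu[itu.index(it), iu]
                        cl = vl[itl.index(it), il]
                        amp += (cu * cl * ((-1.0) ** (upper.J + it + Fl + 1))
                                * _sixj(upper.J, Fu, it, Fl, lower.J, 1))
                    strength = (2 * Fu + 1) * (2 * Fl + 1) * amp * amp
                    if strength < 1e-14:
                        continue
                    comps.append(HyperfineComponent(
                        upper=(upper.J, upper.Ka, upper.Kc, labu[iu], Fu),
                        lower=(lower.J, lower.Ka, lower.Kc, labl[il], Fl),
                        offset=wu[iu] - wl[il],
                        intensity=strength,
                        upper_weights=tuple(
                            (it, float(vu[k, iu]**2))
                            for k, it in enumerate(itu)),
                        lower_weights=tuple(
                            (it, float(vl[k, il]**2))
                            for k, it in enumerate(itl)),
                    ))
    total = sum(c.intensity for c in comps)
    if total <= 0:
        return [HyperfineComponent(
            upper=(upper.J, upper.Ka, upper.Kc, None, None),
            lower=(lower.J, lower.Ka, lower.Kc, None, None),
            offset=0.0, intensity=1.0)]
    return [replace(c, intensity=c.intensity / total) for c in comps]
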