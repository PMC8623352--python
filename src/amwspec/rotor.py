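"""Asymmetric-rotor energy levels and inertial quantities.

Implements the Watson A-reduced rotational Hamiltonian in representation
I^r (inertial a axis mapped to the quantization axis z), with quartic
centrifugal distortion and the sextic term H_K.  Energy levels are
obtained by Wang symmetrization of the signed-k symmetric-top basis and
diagonalization of the four symmetry blocks; (Ka, Kc) labels are assigned
by energy order within each J.

Moments of inertia, planar moments and the inertial defect are derived
from rotational constants through a fixed frequency-to-moment conversion
constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "CONVERSION_CONSTANT",
    "RotationalConstants",
    "DistortionSet",
    "RotationalLevel",
    "MomentsOfInertia",
    "PlanarMoments",
    "moments_from_constants",
    "inertial_defect",
    "planar_moments",
    "energy_levels",
    "AsymmetricRotor",
    "ka_kc_ladder",
]

#: Conversion between rotational constants (MHz) and moments of inertia
#: (u Å^2): I_g = CONVERSION_CONSTANT / X_g.
CONVERSION_CONSTANT = 505379.07  # MHz * u * Angstrom^2

# Unit conversions applied at the I/O boundary; internal unit is MHz.
KHZ = 1e-3
HZ = 1e-6


class InvalidInputError(ValueError):
    """Raised when an operation receives arguments outside its contract."""


@dataclass(frozen=True)
class RotationalConstants:
    """Rigid-rotor constants of one vibronic state, in MHz, A >= B >= C > 0."""

    A: float
    B: float
    C: float
    state_label: str = "ground"

    def __post_init__(self):
        if not (self.A > 0 and self.B > 0 and self.C > 0):
            raise InvalidInputError("rotational constants must be positive")
        if not (self.A >= self.B >= self.C):
            raise InvalidInputError("require A >= B >= C")


@dataclass(frozen=True)
class DistortionSet:
    """Quartic + sextic (H_K only) distortion constants.

    Quartics are in kHz and H_K in Hz, mirroring the usual tabulation;
    they are converted to MHz internally.  Only Watson's A reduction in
    representation I^r is supported.
    """

    delta_J: float = 0.0      # kHz
    delta_JK: float = 0.0     # kHz
    delta_K: float = 0.0      # kHz
    small_delta_J: float = 0.0  # kHz
    small_delta_K: float = 0.0  # kHz
    H_K: float = 0.0          # Hz
    reduction: str = "A"
    representation: str = "Ir"

    def __post_init__(self):
        if self.reduction != "A":
            raise InvalidInputError(
                f"only the A reduction is supported, got {self.reduction!r}")
        if self.representation != "Ir":
            raise InvalidInputError(
                f"only representation Ir is supported, got {self.representation!r}")

    def in_mhz(self) -> tuple[float, float, float, float, float, float]:
        return (self.delta_J * KHZ, self.delta_JK * KHZ, self.delta_K * KHZ,
                self.small_delta_J * KHZ, self.small_delta_K * KHZ,
                self.H_K * HZ)


@dataclass(frozen=True)
class RotationalLevel:
    """One rotational level; energy in MHz relative to 0_00 of its state."""

    J: int
    Ka: int
    Kc: int
    energy: float
    state_label: str = "ground"

    def __post_init__(self):
        if self.J < 0 or not (0 <= self.Ka <= self.J) or not (0 <= self.Kc <= self.J):
            raise InvalidInputError("invalid quantum numbers")
        if self.Ka + self.Kc not in (self.J, self.J + 1):
            raise InvalidInputError("require Ka + Kc in {J, J+1}")

    @property
    def tau(self) -> int:
        return self.Ka - self.Kc


@dataclass(frozen=True)
class MomentsOfInertia:
    """Principal moments in u Å^2, ordered Ia <= Ib <= Ic."""

    Ia: float
    Ib: float
    Ic: float
    conversion_constant: float = CONVERSION_CONSTANT

    def __post_init__(self):
        if not (self.Ia <= self.Ib <= self.Ic):
            raise InvalidInputError("require Ia <= Ib <= Ic")


@dataclass(frozen=True)
class PlanarMoments:
    """Planar moments P_g = (sum of the other two moments - I_g) / 2."""

    Pa: float
    Pb: float
    Pc: float


def moments_from_constants(rc: RotationalConstants,
                           conversion_constant: float = CONVERSION_CONSTANT
                           ) -> MomentsOfInertia:
    """Moments of inertia (u Å^2) from rotational constants (MHz)."""
    return MomentsOfInertia(
        Ia=conversion_constant / rc.A,
        Ib=conversion_constant / rc.B,
        Ic=conversion_constant / rc.C,
        conversion_constant=conversion_constant,
    )


def inertial_defect(m: MomentsOfInertia) -> float:
    """Inertial defect Delta_i = Ic - Ia - Ib (u Å^2); ~0 for planar bodies."""
    return m.Ic - m.Ia - m.Ib


def planar_moments(m: MomentsOfInertia) -> PlanarMoments:
    """Planar moments; Pc = -Delta_i/2 vanishes for a planar rigid body."""
    return PlanarMoments(
        Pa=(-m.Ia + m.Ib + m.Ic) / 2.0,
        Pb=(m.Ia - m.Ib + m.Ic) / 2.0,
        Pc=(m.Ia + m.Ib - m.Ic) / 2.0,
    )


# --------------------------------------------------------------------------
# Watson A-reduced Hamiltonian, representation I^r
# --------------------------------------------------------------------------

def _ladder_factor(J: int, k: int) -> float:
    """sqrt[(J(J+1)-k(k+1)) (J(J+1)-(k+1)(k+2))], the |k> -> |k+2> factor."""
    jj = J * (J + 1)
    return np.sqrt(max(jj - k * (k + 1), 0.0) * max(jj - (k + 1) * (k + 2), 0.0))


def watson_a_matrix(J: int, rc: RotationalConstants, d: DistortionSet) -> np.ndarray:
    """Hamiltonian matrix (MHz) in the signed-k basis k = -J..J.

    Representation I^r: z = a, x = b, y = c.  Includes the quartic
    A-reduction terms and the sextic H_K Jz^6 term.
    """
    dJ, dJK, dK, sdJ, sdK, hK = d.in_mhz()
    A, B, C = rc.A, rc.B, rc.C
    n = 2 * J + 1
    jj = float(J * (J + 1))
    H = np.zeros((n, n))
    ks = np.arange(-J, J + 1)
    H[np.diag_indices(n)] = (0.5 * (B + C) * (jj - ks**2) + A * ks**2
                             - dJ * jj**2 - dJK * jj * ks**2 - dK * ks**4
                             + hK * ks.astype(float)**6)
    for i, k in enumerate(ks[:-2]):
        off = (0.25 * (B - C) - sdJ * jj
               - 0.5 * sdK * (k**2 + (k + 2)**2)) * _ladder_factor(J, k)
        H[i, i + 2] = H[i + 2, i] = off
    return H


@lru_cache(maxsize=256)
def _wang_matrix(J: int) -> np.ndarray:
    """Orthogonal Wang transform: signed-k basis -> (|k> +/- |-k>)/sqrt(2).

    Column order: K = 0 (J even part only for K=0), then for K = 1..J the
    '+' combination followed by the '-' combination.
    """
    n = 2 * J + 1
    W = np.zeros((n, n))
    idx = {k: k + J for k in range(-J, J + 1)}
    col = 0
    W[idx[0], col] = 1.0
    col += 1
    for K in range(1, J + 1):
        s = 1.0 / np.sqrt(2.0)
        W[idx[K], col] = s
        W[idx[-K], col] = s
        col += 1
        W[idx[K], col] = s
        W[idx[-K], col] = -s
        col += 1
    return W


def _wang_block_indices(J: int) -> list[np.ndarray]:
    """Index sets of the four Wang symmetry blocks (E+, E-, O+, O-)."""
    # Column layout of _wang_matrix: 0 -> K=0(+); then (K,+), (K,-) pairs.
    eplus, eminus, oplus, ominus = [0], [], [], []
    col = 1
    for K in range(1, J + 1):
        if K % 2 == 0:
            eplus.append(col)
            eminus.append(col + 1)
        else:
            oplus.append(col)
            ominus.append(col + 1)
        col += 2
    return [np.array(b, dtype=int) for b in (eplus, eminus, oplus, ominus) if b]


def ka_kc_ladder(J: int) -> list[tuple[int, int]]:
    """Standard (Ka, Kc) assignment ladder in ascending energy order."""
    return [((J + tau + 1) // 2, (J - tau + 1) // 2) for tau in range(-J, J + 1)]


class AsymmetricRotor:
    """Eigen-solver for one vibronic state with cached per-J eigensystems.

    Eigenvectors are stored in the signed-k basis (columns ordered by
    ascending energy, i.e. by tau = Ka - Kc) so that downstream code can
    form dipole and field-gradient matrix elements.
    """

    def __init__(self, rc: RotationalConstants, d: DistortionSet | None = None):
        self.rc = rc
        self.d = d if d is not None else DistortionSet()
        self._cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def eigensystem(self, J: int) -> tuple[np.ndarray, np.ndarray]:
        """(energies, vectors) for all 2J+1 levels of J, sorted by energy."""
        if J < 0:
            raise InvalidInputError("J must be >= 0")
        if J in self._cache:
            return self._cache[J]
        H = watson_a_matrix(J, self.rc, self.d)
        W = _wang_matrix(J)
        Hw = W.T @ H @ W
        n = 2 * J + 1
        energies = np.empty(n)
        vectors = np.empty((n, n))
        pos = 0
        block_id = np.empty(n, dtype=int)
        for bi, block in enumerate(_wang_block_indices(J)):
            sub = Hw[np.ix_(block, block)]
            w, v = np.linalg.eigh(sub)
            m = len(block)
            energies[pos:pos + m] = w
            full = np.zeros((n, m))
            full[block, :] = v
            vectors[:, pos:pos + m] = W @ full
            block_id[pos:pos + m] = bi
            pos += m
        # stable sort: energy, then Wang block (breaks exact degeneracies)
        order = np.lexsort((block_id, np.round(energies, 9)))
        res = (energies[order], vectors[:, order])
        self._cache[J] = res
        return res

    def levels(self, J_max: int) -> list[RotationalLevel]:
        if J_max < 0:
            raise InvalidInputError("J_max must be >= 0")
        out = []
        e000 = self.eigensystem(0)[0][0]
        for J in range(J_max + 1):
            energies, _ = self.eigensystem(J)
            for (ka, kc), e in zip(ka_kc_ladder(J), energies):
                out.append(RotationalLevel(J=J, Ka=ka, Kc=kc,
                                           energy=e - e000,
                                           state_label=self.rc.state_label))
        return out

    def level_index(self, J: int, Ka: int, Kc: int) -> int:
        ladder = ka_kc_ladder(J)
        try:
            return ladder.index((Ka, Kc))
        except ValueError:
            raise InvalidInputError(f"no level {J}_{Ka}{Kc}") from None

    def level_energy(self, J: int, Ka: int, Kc: int) -> float:
        energies, _ = self.eigensystem(J)
        return energies[self.level_index(J, Ka, Kc)] - self.eigensystem(0)[0][0]

    def level_vector(self, J: int, Ka: int, Kc: int) -> np.ndarray:
        _, vectors = self.eigensystem(J)
        return vectors[:, self.level_index(J, Ka, Kc)]

    def jg_squared(self, J: int, Ka: int, Kc: int) -> tuple[float, float, float]:
        """Expectation values (<Ja^2>, <Jb^2>, <Jc^2>) for one level."""
        if J == 0:
            return (0.0, 0.0, 0.0)
        v = self.level_vector(J, Ka, Kc)
        ks = np.arange(-J, J + 1)
        ja2 = float(np.sum(v**2 * ks**2))
        # <Jb^2 - Jc^2> from the (k, k+2) ladder structure
        off = np.array([_ladder_factor(J, k) for k in ks[:-2]])
        jb2_minus_jc2 = float(np.sum(v[:-2] * v[2:] * off))
        jj = J * (J + 1)
        jb2 = 0.5 * (jj - ja2 + jb2_minus_jc2)
        jc2 = 0.5 * (jj - ja2 - jb2_minus_jc2)
        return (ja2, jb2, jc2)


def energy_levels(rc: RotationalConstants, d: DistortionSet | None = None,
                  J_max: int = 10) -> list[RotationalLevel]:
    """Rotational levels up to J_max, energies relative to 0_00 (MHz)."""
    return AsymmetricRotor(rc, d).levels(J_max)
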