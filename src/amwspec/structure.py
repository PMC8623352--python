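"""Geometry handling and effective (r0) structure determination.

Rigid-body mechanics on atomic Cartesian geometries: principal moments,
isotopic substitution, per-axis scaling of a geometry to target planar
moments (the standard trick for making an approximate monomer geometry
reproduce experimental ground-state rotational constants), assembly of a
planar-molecule + water cluster from three intermolecular parameters, and
a least-squares fit of those parameters to isotopologue moments of
inertia.

The cluster model places the water oxygen in the plane of the aromatic
partner at a distance d(O...Nr) from the ring nitrogen and an angle
A(O...Nr-C2) to the Nr-C2 direction; the water hydrogen donated to Nr
lies on the O...Nr line (optionally deviated by a fixed hydrogen-bond
nonlinearity angle, kept in the molecular plane) and the remaining
orientation is set by the dihedral D(HOH...Nr), measured here as the
dihedral angle H2-O-Nr-C2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import brentq, least_squares

from .rotor import (CONVERSION_CONSTANT, InvalidInputError, MomentsOfInertia,
                    PlanarMoments, planar_moments)

__all__ = [
    "ATOMIC_MASSES",
    "Geometry",
    "ClusterParams",
    "StructureFitResult",
    "read_xyz",
    "write_xyz",
    "principal_moments",
    "to_principal_frame",
    "make_isotopologue",
    "scale_geometry_to_planar_moments",
    "assemble_cluster",
    "measure_cluster_params",
    "r0_fit",
    "dihedral_angle",
]


def _load_masses() -> dict[str, float]:
    text = resources.files("amwspec.data").joinpath("masses.yaml").read_text()
    return yaml.safe_load(text)["masses"]


#: Isotopic masses in u, keyed by isotope symbol; plain element symbols
#: map to the most abundant isotope.
ATOMIC_MASSES: dict[str, float] = _load_masses()


@dataclass(frozen=True)
class Geometry:
    """Atoms with isotope masses (u) and Cartesian coordinates (Å).

    names are optional per-atom role labels ("Nr", "C2", "H5", ...) used
    by the cluster-assembly and substitution operations.
    """

    elements: tuple[str, ...]
    masses: np.ndarray
    coords: np.ndarray
    names: tuple[str, ...] = ()
    frame: str = "arbitrary"

    def __post_init__(self):
        object.__setattr__(self, "masses", np.asarray(self.masses, float))
        object.__setattr__(self, "coords",
                           np.asarray(self.coords, float).reshape(-1, 3))
        if np.any(self.masses <= 0):
            raise InvalidInputError("atomic masses must be positive")
        if len(self.masses) != len(self.coords) != len(self.elements):
            raise InvalidInputError("inconsistent atom count")
        if self.names and len(self.names) != len(self.elements):
            raise InvalidInputError("names must match atom count")

    def __len__(self) -> int:
        return len(self.elements)

    def index(self, name: str) -> int:
        if not self.names:
            raise InvalidInputError("geometry carries no atom names")
        try:
            return self.names.index(name)
        except ValueError:
            raise InvalidInputError(f"no atom named {name!r}") from None

    def position(self, name: str) -> np.ndarray:
        return self.coords[self.index(name)]

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    @property
    def center_of_mass(self) -> np.ndarray:
        return np.average(self.coords, axis=0, weights=self.masses)


def read_xyz(path_or_text, default_masses: dict[str, float] | None = None
             ) -> Geometry:
    """Read an extended XYZ file: element x y z [mass] [name] per atom."""
    import os
    if isinstance(path_or_text, (str, os.PathLike)) and "\n" not in str(path_or_text):
        with open(path_or_text) as fh:
            text = fh.read()
    else:
        text = str(path_or_text)
    lines = [l for l in text.splitlines()]
    n = int(lines[0].split()[0])
    table = default_masses or ATOMIC_MASSES
    elements, masses, coords, names = [], [], [], []
    for raw in lines[2:2 + n]:
        parts = raw.split()
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
        mass = float(parts[4]) if len(parts) > 4 else table[parts[0]]
        masses.append(mass)
        names.append(parts[5] if len(parts) > 5 else parts[0])
    return Geometry(tuple(elements), np.array(masses), np.array(coords),
                    tuple(names))


def write_xyz(g: Geometry, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(g)}\n{comment}\n")
        for i in range(len(g)):
            name = g.names[i] if g.names else g.elements[i]
            x, y, z = g.coords[i]
            fh.write(f"{g.elements[i]:3s} {x:13.8f} {y:13.8f} {z:13.8f} "
                     f"{g.masses[i]:11.6f} {name}\n")


# --------------------------------------------------------------------------
# Principal-axis mechanics
# --------------------------------------------------------------------------

def _inertia_tensor(masses: np.ndarray, coords: np.ndarray) -> np.ndarray:
    r2 = np.sum(coords**2, axis=1)
    I = np.eye(3) * np.sum(masses * r2)
    I -= np.einsum("i,ij,ik->jk", masses, coords, coords)
    return I


def principal_moments(g: Geometry) -> tuple[MomentsOfInertia, np.ndarray]:
    """Principal moments (u Å^2, Ia <= Ib <= Ic) and the rotation matrix
    whose rows are the principal axes in the input frame."""
    if len(g) < 2:
        raise InvalidInputError("moments undefined for a single atom")
    coords = g.coords - g.center_of_mass
    I = _inertia_tensor(g.masses, coords)
    w, V = np.linalg.eigh(I)
    m = MomentsOfInertia(Ia=float(w[0]), Ib=float(w[1]), Ic=float(w[2]))
    return m, V.T


def to_principal_frame(g: Geometry) -> Geometry:
    """Shift to the center of mass and rotate to principal axes (a, b, c).

    Axis signs are fixed deterministically: each axis is flipped so the
    mass-weighted cube of coordinates along it is non-negative, and the
    system is kept right-handed by flipping c if needed.
    """
    coords = g.coords - g.center_of_mass
    _, axes = principal_moments(g)
    axes = axes.copy()
    for k in range(3):
        proj = coords @ axes[k]
        s = float(np.sum(g.masses * proj**3))
        if s < 0 or (s == 0 and proj[np.argmax(np.abs(proj))] < 0):
            axes[k] *= -1
    if np.linalg.det(axes) < 0:  # keep (a, b, c) right-handed
        axes[2] *= -1
    return Geometry(g.elements, g.masses.copy(), coords @ axes.T, g.names,
                    frame="principal")


def make_isotopologue(g: Geometry, substitutions) -> Geometry:
    """Replace isotope masses at the given atoms; coordinates untouched.

    substitutions: iterable of (atom index or atom name, new mass in u).
    """
    masses = g.masses.copy()
    for key, new_mass in substitutions:
        idx = g.index(key) if isinstance(key, str) else int(key)
        if not 0 <= idx < len(g):
            raise InvalidInputError(f"atom index {idx} out of range")
        masses[idx] = new_mass
    return Geometry(g.elements, masses, g.coords.copy(), g.names, g.frame)


def scale_geometry_to_planar_moments(g: Geometry, target: PlanarMoments
                                     ) -> tuple[Geometry, np.ndarray, list[str]]:
    """Scale each principal-axis coordinate so planar moments match targets.

    P_g = sum_i m_i g_i^2, so the factor along axis g is
    sqrt(target_P_g / current_P_g).  Axes whose current planar moment is
    (near) zero while the target is not cannot be matched by scaling;
    they are flagged and left unscaled.  Returns (scaled geometry,
    factors, flags).
    """
    if g.frame != "principal":
        raise InvalidInputError("geometry must be in the principal frame")
    coords = g.coords.copy()
    current = np.array([float(np.sum(g.masses * coords[:, k]**2))
                        for k in range(3)])
    targets = np.array([target.Pa, target.Pb, target.Pc])
    factors = np.ones(3)
    flags = []
    for k, axis in enumerate("abc"):
        if targets[k] < 0:
            flags.append(f"P{axis}: negative target, axis left unscaled")
        elif current[k] <= 1e-12:
            if targets[k] > 1e-12:
                flags.append(f"P{axis}: zero planar moment, axis left unscaled")
        else:
            factors[k] = math.sqrt(targets[k] / current[k])
    coords *= factors
    return (Geometry(g.elements, g.masses.copy(), coords, g.names,
                     frame="principal"), factors, flags)


# --------------------------------------------------------------------------
# Cluster assembly
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterParams:
    """The three fitted intermolecular parameters plus frozen assumptions."""

    d_O_Nr: float                  # Å
    angle_O_Nr_C2: float           # degrees, angle at Nr
    dihedral_HOH_Nr: float         # degrees, dihedral H2-O-Nr-C2
    nonlinearity: float = 0.0      # degrees, in-plane O-H1...Nr deviation
    in_plane: bool = True

    def __post_init__(self):
        if self.d_O_Nr <= 0:
            raise InvalidInputError("distance must be positive")
        if not 0.0 < self.angle_O_Nr_C2 < 180.0:
            raise InvalidInputError("angle must be in (0, 180) degrees")


@dataclass
class StructureFitResult:
    params: ClusterParams
    std_errors: dict
    sigma_fit: float               # rms of residuals, u Å^2
    sigma_fit_dof: float           # sqrt(SSR/(N-p)), u Å^2
    residuals: "object"            # DataFrame: isotopologue, moment, obs, o-c
    converged: bool
    message: str = ""


def _rot_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return (np.eye(3) + math.sin(angle_rad) * K
            + (1 - math.cos(angle_rad)) * (K @ K))


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral (degrees, IUPAC right-hand convention) of p1-p2-p3-p4."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))


def _water_internal(water: Geometry) -> tuple[float, float, float]:
    """(r_OH1, r_OH2, HOH angle in rad) from a water fixture geometry."""
    o = water.position("O")
    h1 = water.position("H1") - o
    h2 = water.position("H2") - o
    r1, r2 = np.linalg.norm(h1), np.linalg.norm(h2)
    theta = math.acos(float(np.dot(h1, h2)) / (r1 * r2))
    return float(r1), float(r2), theta


def assemble_cluster(amp: Geometry, water: Geometry, p: ClusterParams,
                     planarity_tol: float = 0.5) -> Geometry:
    """Rigidly attach a water molecule to a (near-)planar partner.

    Works in the partner's principal frame (molecular plane = ab).  The
    oxygen is placed in that plane at distance d from Nr, on the amino
    side of the Nr->C2 direction; H1 points from O toward Nr (deviated
    in-plane by the fixed nonlinearity angle); H2 completes the rigid
    water with the requested H2-O-Nr-C2 dihedral.
    """
    amp_p = to_principal_frame(amp) if amp.frame != "principal" else amp
    c_extent = float(np.max(np.abs(amp_p.coords[:, 2])))
    if c_extent > planarity_tol:
        raise InvalidInputError("partner geometry is not close to planar")
    nr = amp_p.position("Nr")
    c2 = amp_p.position("C2")
    na = amp_p.position("Na")
    chat = np.array([0.0, 0.0, 1.0])

    # oxygen exactly in the ab plane (z = 0), at exact distance and angle:
    # O = Nr + d*u with u_z fixed by the plane condition, |u| = 1 and
    # u.v = cos(angle) where v points from Nr to C2
    v = (c2 - nr) / np.linalg.norm(c2 - nr)
    uz = -nr[2] / p.d_O_Nr
    h = math.cos(math.radians(p.angle_O_Nr_C2)) - uz * v[2]
    pxy = v[:2]
    pn2 = float(pxy @ pxy)
    r2_xy = 1.0 - uz * uz
    t2 = r2_xy - h * h / pn2
    if t2 < 0:
        raise InvalidInputError("cluster parameters place the oxygen "
                                "outside the molecular plane")
    q = np.array([-pxy[1], pxy[0]]) / math.sqrt(pn2)
    base = (h / pn2) * pxy
    t = math.sqrt(t2)
    cand = [np.array([*(base + s * t * q), uz]) for s in (+1.0, -1.0)]
    u = min(cand, key=lambda x: np.linalg.norm(nr + p.d_O_Nr * x - na))
    o = nr + p.d_O_Nr * u

    r1, r2, theta = _water_internal(water)
    d1 = (nr - o) / np.linalg.norm(nr - o)
    if p.nonlinearity != 0.0:
        # deviate toward the molecular plane normal's in-plane complement:
        # rotation axis is the component of c perpendicular to the O->Nr
        # direction, so the deviation angle is exact and stays (near) the
        # molecular plane
        axis = chat - float(chat @ d1) * d1
        d1 = _rot_about(axis, math.radians(p.nonlinearity)) @ d1
    h1 = o + r1 * d1

    # basis perpendicular to the O-H1 direction
    e1 = chat - np.dot(chat, d1) * d1
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d1, e1)

    def h2_at(phi: float) -> np.ndarray:
        v = (math.cos(theta) * d1
             + math.sin(theta) * (math.cos(phi) * e1 + math.sin(phi) * e2))
        return o + r2 * v

    target = p.dihedral_HOH_Nr

    def mismatch(phi: float) -> float:
        dd = dihedral_angle(h2_at(phi), o, nr, c2) - target
        return (dd + 180.0) % 360.0 - 180.0

    grid = np.linspace(-math.pi, math.pi, 73)
    vals = np.array([mismatch(x) for x in grid])
    phi_sol = None
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            phi_sol = grid[i]
            break
        if vals[i] * vals[i + 1] < 0 and abs(vals[i] - vals[i + 1]) < 180.0:
            phi_sol = brentq(mismatch, grid[i], grid[i + 1], xtol=1e-14)
            break
    if phi_sol is None:
        raise InvalidInputError("could not realize the requested dihedral")
    h2 = h2_at(phi_sol)

    elements = amp_p.elements + ("O", "H", "H")
    masses = np.concatenate([amp_p.masses,
                             [water.masses[water.index("O")],
                              water.masses[water.index("H1")],
                              water.masses[water.index("H2")]]])
    coords = np.vstack([amp_p.coords, o, h1, h2])
    names = tuple(amp_p.names) + ("O", "H1", "H2")
    return Geometry(elements, masses, coords, names, frame="arbitrary")


def measure_cluster_params(cluster: Geometry) -> ClusterParams:
    """Re-measure (d, angle, dihedral) from an assembled cluster."""
    o, nr, c2 = (cluster.position(n) for n in ("O", "Nr", "C2"))
    h2 = cluster.position("H2")
    d = float(np.linalg.norm(o - nr))
    v1 = (o - nr) / np.linalg.norm(o - nr)
    v2 = (c2 - nr) / np.linalg.norm(c2 - nr)
    ang = math.degrees(math.acos(float(np.clip(np.dot(v1, v2), -1, 1))))
    dih = dihedral_angle(h2, o, nr, c2)
    return ClusterParams(d_O_Nr=d, angle_O_Nr_C2=ang, dihedral_HOH_Nr=dih)


# --------------------------------------------------------------------------
# r0 least-squares structure fit
# --------------------------------------------------------------------------

def cluster_moments(amp: Geometry, water: Geometry, p: ClusterParams,
                    substitutions=()) -> MomentsOfInertia:
    """Moments of one (isotopically substituted) assembled cluster."""
    cluster = assemble_cluster(amp, water, p)
    if substitutions:
        cluster = make_isotopologue(cluster, substitutions)
    m, _ = principal_moments(cluster)
    return m


def r0_fit(amp: Geometry, water: Geometry, p0: ClusterParams,
           isotopologues: list[tuple[str, list]],
           observed: np.ndarray, weights: np.ndarray | None = None,
           fix_dihedral: bool = False) -> StructureFitResult:
    """Fit (d, angle, dihedral) to isotopologue moments of inertia.

    observed is an (n_iso, 3) array of (Ia, Ib, Ic) in u Å^2 matching the
    isotopologue list; weights (optional, same shape) multiply the
    residuals.  Standard errors are statistical, scaled by the residual
    variance as structure-fit programs conventionally report them.
    """
    observed = np.asarray(observed, float).reshape(len(isotopologues), 3)
    w = (np.ones_like(observed) if weights is None
         else np.asarray(weights, float).reshape(observed.shape))
    names = ["d_O_Nr", "angle_O_Nr_C2"] + \
        ([] if fix_dihedral else ["dihedral_HOH_Nr"])

    def make_params(x):
        kw = dict(d_O_Nr=x[0], angle_O_Nr_C2=x[1],
                  dihedral_HOH_Nr=(p0.dihedral_HOH_Nr if fix_dihedral else x[2]),
                  nonlinearity=p0.nonlinearity, in_plane=p0.in_plane)
        return ClusterParams(**kw)

    def residuals(x):
        p = make_params(x)
        rows = []
        for (_, subs), obs_row, w_row in zip(isotopologues, observed, w):
            m = cluster_moments(amp, water, p, subs)
            model = np.array([m.Ia, m.Ib, m.Ic])
            rows.append((model - obs_row) * w_row)
        return np.concatenate(rows)

    x0 = [p0.d_O_Nr, p0.angle_O_Nr_C2] + \
        ([] if fix_dihedral else [p0.dihedral_HOH_Nr])
    res = least_squares(residuals, np.array(x0, float), method="lm",
                        xtol=1e-12, ftol=1e-12, gtol=1e-14,
                        x_scale=np.maximum(np.abs(x0), 1.0))
    r = res.fun
    n, npar = r.size, len(x0)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        u, s, _ = np.linalg.svd(jtj)
        bad = [names[i] for i in np.argsort(np.abs(u[:, -1]))[::-1][:1]]
        raise InvalidInputError(
            f"rank-deficient structure fit; undetermined: {bad}")
    ssr = float(np.sum(r**2))
    s2 = ssr / max(n - npar, 1)
    std = dict(zip(names, np.sqrt(np.diag(cov) * s2)))

    import pandas as pd
    p_fit = make_params(res.x)
    rows = []
    for (label, subs), obs_row in zip(isotopologues, observed):
        m = cluster_moments(amp, water, p_fit, subs)
        for axis, model, obs in zip("abc", (m.Ia, m.Ib, m.Ic), obs_row):
            rows.append({"isotopologue": label, "moment": f"I{axis}",
                         "obs": obs, "calc": model, "obs_minus_calc":
                         obs - model})
    table = pd.DataFrame(rows)
    return StructureFitResult(
        params=p_fit, std_errors=std,
        sigma_fit=float(np.sqrt(np.mean(r**2))),
        sigma_fit_dof=float(np.sqrt(s2)),
        residuals=table, converged=bool(res.success), message=res.message)
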