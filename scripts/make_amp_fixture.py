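"""Regenerate the synthetic 2-aminopyridine fixture geometry.

The stand-in is constructed from the experimental effective (r0) ring
structure of pyridine (C2v: r(N-C2) 1.3376 Å, r(C2-C3) 1.3938 Å,
r(C3-C4) 1.3916 Å; angles C2-N-C6 116.94°, N-C2-C3 123.80°, C2-C3-C4
118.53°) with an amino group at the 2-position (r(C-N) 1.375 Å, slightly
pyramidal NH2), and then refined against the nine ground-state moments
of inertia of the parent, 5-d and 6-d monomer isotopologues: one scale
factor per principal axis plus in-plane shifts of the H5/H6 atoms, which
the deuterium data pin directly.

Run from the repository root:  python scripts/make_amp_fixture.py
"""

import math

import numpy as np
from scipy.optimize import least_squares

from amwspec.datasets import state_constants
from amwspec.rotor import moments_from_constants
from amwspec.structure import (Geometry, make_isotopologue, principal_moments,
                               to_principal_frame, write_xyz)

DEG = math.pi / 180.0
MASS = {"N": 14.003074, "C": 12.0, "H": 1.007825}
MASS_D = 2.014102


def rot2(v, ang):
    c, s = math.cos(ang), math.sin(ang)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def ext_bisector(center, n1, n2, r):
    d1 = (n1 - center) / np.linalg.norm(n1 - center)
    d2 = (n2 - center) / np.linalg.norm(n2 - center)
    b = -(d1 + d2)
    return center + r * b / np.linalg.norm(b)


def idealized_geometry() -> Geometry:
    rNC2, rC2C3, rC3C4 = 1.3376, 1.3938, 1.3916
    aC2NC6, aNC2C3, aC2C3C4 = 116.94, 123.80, 118.53
    half = aC2NC6 / 2 * DEG
    N1 = np.array([0.0, 0.0])
    C2 = np.array([rNC2 * math.cos(half), rNC2 * math.sin(half)])
    C6 = np.array([C2[0], -C2[1]])
    dirN = (N1 - C2) / np.linalg.norm(N1 - C2)
    C3 = C2 + rC2C3 * rot2(dirN, aNC2C3 * DEG)
    dirC2 = (C2 - C3) / np.linalg.norm(C2 - C3)
    C4 = C3 + rC3C4 * rot2(dirC2, aC2C3C4 * DEG)
    C5 = np.array([C3[0], -C3[1]])
    H3 = ext_bisector(C3, C2, C4, 1.0826)
    H4 = ext_bisector(C4, C3, C5, 1.0818)
    H5 = np.array([H3[0], -H3[1]])
    H6 = ext_bisector(C6, N1, C5, 1.0865)
    Na = ext_bisector(C2, N1, C3, 1.375)
    dna = (Na - C2) / np.linalg.norm(Na - C2)
    r_xy = math.sqrt(1.005**2 - 0.26**2)
    HNa1 = np.concatenate([Na + r_xy * rot2(dna, 56.5 * DEG), [0.26]])
    HNa2 = np.concatenate([Na + r_xy * rot2(dna, -56.5 * DEG), [0.26]])
    atoms = {"Nr": N1, "C2": C2, "C3": C3, "C4": C4, "C5": C5, "C6": C6,
             "H3": H3, "H4": H4, "H5": H5, "H6": H6, "Na": Na}
    elems, names, coords, masses = [], [], [], []
    for n, p in atoms.items():
        elems.append(n[0])
        names.append(n)
        coords.append([p[0], p[1], 0.0])
        masses.append(MASS[n[0]])
    for n, p in (("H_Na1", HNa1), ("H_Na2", HNa2)):
        elems.append("H")
        names.append(n)
        coords.append(list(p))
        masses.append(MASS["H"])
    return to_principal_frame(Geometry(tuple(elems), np.array(masses),
                                       np.array(coords), tuple(names)))


def refine(g0: Geometry) -> Geometry:
    obs = []
    for state in ("parent", "d5", "d6"):
        rc, _ = state_constants("amp", state)
        m = moments_from_constants(rc)
        obs.append([m.Ia, m.Ib, m.Ic])
    obs = np.array(obs)
    i5, i6 = g0.index("H5"), g0.index("H6")

    def build(x):
        sa, sb, sc, dx5, dy5, dx6, dy6 = x
        c = g0.coords.copy()
        c[:, 0] *= sa
        c[:, 1] *= sb
        c[:, 2] *= sc
        c[i5, 0] += dx5
        c[i5, 1] += dy5
        c[i6, 0] += dx6
        c[i6, 1] += dy6
        return Geometry(g0.elements, g0.masses.copy(), c, g0.names)

    def resid(x):
        rows = []
        for subs in ([], [(i5, MASS_D)], [(i6, MASS_D)]):
            m, _ = principal_moments(make_isotopologue(build(x), subs))
            rows.append([m.Ia, m.Ib, m.Ic])
        return (np.array(rows) - obs).ravel()

    res = least_squares(resid, [1, 1, 1, 0, 0, 0, 0], method="lm",
                        xtol=1e-14, ftol=1e-14)
    rms = float(np.sqrt(np.mean(resid(res.x) ** 2)))
    print("axis scales:", np.round(res.x[:3], 5),
          "H5/H6 shifts:", np.round(res.x[3:], 4))
    print(f"monomer-moment rms: {rms:.5f} uA^2")
    return to_principal_frame(build(res.x))


if __name__ == "__main__":
    g = refine(idealized_geometry())
    write_xyz(g, "src/amwspec/data/amp_synthetic.xyz",
              "synthetic stand-in geometry for 2-aminopyridine: experimental "
              "pyridine ring + standard amino substitution, axis-scaled and "
              "H5/H6-refined to ground-state monomer isotopologue moments")
    print("wrote src/amwspec/data/amp_synthetic.xyz")
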