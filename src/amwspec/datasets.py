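"""Shipped reference constants and fixture geometries.

The package carries the published spectroscopic constants of
2-aminopyridine (AMP) and of its 1:1 water cluster (AMW) as plain-text
config, together with two fixture geometries: an effective ground-state
water monomer and a synthetic force-field stand-in for AMP meant to be
scaled to the experimental planar moments before quantitative use.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .hyperfine import HyperfineFitParams, QuadrupoleTensor
from .rotor import DistortionSet, RotationalConstants
from .structure import Geometry, read_xyz

__all__ = [
    "load_constants",
    "state_constants",
    "hyperfine_params",
    "quad_tensor",
    "dipoles",
    "amw_experimental_moments",
    "amp_geometry",
    "water_geometry",
    "QUAD_SCALING_FACTOR",
]

_DIST_KEYS = {"DJ": "delta_J", "DJK": "delta_JK", "DK": "delta_K",
              "dJ": "small_delta_J", "dK": "small_delta_K", "HK": "H_K"}


@lru_cache(maxsize=1)
def load_constants() -> dict:
    text = resources.files("amwspec.data").joinpath("constants.yaml").read_text()
    return yaml.safe_load(text)


def state_constants(species: str, state: str
                    ) -> tuple[RotationalConstants, DistortionSet]:
    """Rotational + distortion constants for e.g. ('amp', '0plus')."""
    entry = load_constants()[species][state]
    rc = RotationalConstants(entry["A"], entry["B"], entry["C"],
                             state_label=state)
    dist = DistortionSet(**{_DIST_KEYS[k]: entry[k]
                            for k in _DIST_KEYS if k in entry})
    return rc, dist


def hyperfine_params(species: str, state: str) -> list[HyperfineFitParams]:
    """The fitted hyperfine combinations of both nitrogen nuclei."""
    entry = load_constants()[species][state].get("hyperfine", {})
    out = []
    for nuc in ("Na", "Nr"):
        if nuc in entry:
            d = entry[nuc]
            out.append(HyperfineFitParams(
                three_halves_chi_aa=d["chi32aa"],
                quarter_chi_bb_minus_cc=d["chibbcc4"],
                chi_ab=d.get("chiab", 0.0),
                nucleus_label=nuc))
    return out


def quad_tensor(species: str, nucleus: str, kind: str = "exp"
                ) -> QuadrupoleTensor:
    """Full tensor in inertial axes from the tensor comparison table.

    Tabulated components are rounded independently, so their trace can
    be off by ~1e-4 MHz; the loader removes the residual trace evenly to
    restore the Laplace relation exactly.
    """
    d = load_constants()["tensors"][species][kind][nucleus]
    shift = (d["chi_aa"] + d["chi_bb"] + d["chi_cc"]) / 3.0
    return QuadrupoleTensor(chi_aa=d["chi_aa"] - shift,
                            chi_bb=d["chi_bb"] - shift,
                            chi_cc=d["chi_cc"] - shift,
                            chi_ab=d.get("chi_ab", 0.0),
                            nucleus_label=nucleus)


def dipoles(species: str) -> tuple[float, float, float]:
    d = load_constants()[species]["dipoles"]
    return d["mu_a"], d["mu_b"], d["mu_c"]


def amw_experimental_moments() -> tuple[list[str], np.ndarray]:
    """Isotopologue labels and the nine experimental moments (u Å^2)."""
    m = load_constants()["structure"]["moments"]
    labels = ["parent", "d5", "d6"]
    return labels, np.array([m[l] for l in labels])


QUAD_SCALING_FACTOR = 0.941  # computed-tensor scaling anchored on AMP chi_cc


def _read_fixture(name: str) -> Geometry:
    text = resources.files("amwspec.data").joinpath(name).read_text()
    return read_xyz(text)


@lru_cache(maxsize=1)
def amp_geometry() -> Geometry:
    """Synthetic stand-in geometry of 2-aminopyridine (principal frame).

    Built from the experimental pyridine ring structure with a standard
    amino substitution and refined so the parent, 5-d and 6-d monomer
    moments of inertia are reproduced (see scripts/make_amp_fixture.py);
    a stand-in for the unpublished scaled quantum-chemistry geometry.
    """
    from .structure import to_principal_frame
    return to_principal_frame(_read_fixture("amp_synthetic.xyz"))


@lru_cache(maxsize=1)
def water_geometry() -> Geometry:
    """Effective ground-state water geometry: r(OH) 0.9572 Å, HOH 104.52°."""
    return _read_fixture("water.xyz")
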