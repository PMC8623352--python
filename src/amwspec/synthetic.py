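"""Synthetic-data generators mirroring the study's measurement conditions.

Line lists are generated from known spectroscopic constants with Gaussian
frequency noise at the stated instrumental accuracies (2 kHz for cavity
FTMW, 50 kHz for room-temperature MMW); isotopologue moment sets come
from a known cluster geometry with moment-level noise of order the
structure-fit deviation (0.025 u Å^2).  Every generator is a pure
function of its inputs and an explicit integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .rotor import InvalidInputError, MomentsOfInertia
from .spectra import MeasuredLine, SpectrumModel, Transition, predict_spectrum
from .structure import ClusterParams, Geometry, cluster_moments

__all__ = [
    "NoiseSpec",
    "LineSelection",
    "simulate_linelist",
    "simulate_cluster_moments",
    "toy_planar_molecule",
    "FTMW_SIGMA_MHZ",
    "MMW_SIGMA_MHZ",
    "MOMENT_SIGMA",
]

FTMW_SIGMA_MHZ = 0.002   # 2 kHz cavity FTMW measurement accuracy
MMW_SIGMA_MHZ = 0.050    # 50 kHz MMW measurement accuracy
MOMENT_SIGMA = 0.025     # u Å^2, effective moment-level scatter


@dataclass(frozen=True)
class NoiseSpec:
    """Noise levels and the seed that makes a generator deterministic."""

    frequency_sigma: dict = field(
        default_factory=lambda: {"FTMW": FTMW_SIGMA_MHZ, "MMW": MMW_SIGMA_MHZ})
    moment_sigma: float = MOMENT_SIGMA
    seed: int = 0

    def __post_init__(self):
        if any(s < 0 for s in self.frequency_sigma.values()) or \
                self.moment_sigma < 0:
            raise InvalidInputError("noise sigmas must be non-negative")


@dataclass(frozen=True)
class LineSelection:
    """Which predicted transitions enter a simulated measurement set."""

    f_min: float
    f_max: float
    J_max: int = 10
    J_min: int = 0
    Ka_max: int | None = None
    branches: tuple[str, ...] = ("a", "b", "c")
    max_lines: int | None = None   # keep the strongest n


def simulate_linelist(model: SpectrumModel, selection: LineSelection,
                      noise: NoiseSpec, source: str = "FTMW"
                      ) -> list[MeasuredLine]:
    """Measured-like lines: predictions plus Gaussian noise at the subset
    accuracy; uncertainties are set to that accuracy."""
    trans = predict_spectrum(model, selection.f_min, selection.f_max,
                             J_max=selection.J_max)
    trans = [t for t in trans
             if t.lower[0] >= selection.J_min
             and t.branch in selection.branches
             and (selection.Ka_max is None or
                  max(t.upper[1], t.lower[1]) <= selection.Ka_max)]
    if not trans:
        raise InvalidInputError("selection produced an empty prediction")
    if selection.max_lines is not None:
        trans = sorted(trans, key=lambda t: -t.intensity)[:selection.max_lines]
        trans.sort(key=lambda t: t.frequency)
    sigma = noise.frequency_sigma.get(source)
    if sigma is None:
        raise InvalidInputError(f"no noise level for source {source!r}")
    rng = np.random.default_rng(noise.seed)
    shifts = rng.normal(0.0, sigma, size=len(trans)) if sigma > 0 \
        else np.zeros(len(trans))
    return [MeasuredLine(frequency=t.frequency + dv,
                         uncertainty=max(sigma, 1e-9),
                         upper=t.upper, lower=t.lower,
                         state_label=t.state_label, source=source)
            for t, dv in zip(trans, shifts)]


def simulate_cluster_moments(amp: Geometry, water: Geometry,
                             p: ClusterParams,
                             isotopologues: list[tuple[str, list]],
                             noise: NoiseSpec) -> np.ndarray:
    """Noisy (n_iso, 3) moments from the assemble -> substitute ->
    principal-moments pipeline."""
    clean = []
    for _, subs in isotopologues:
        m = cluster_moments(amp, water, p, subs)
        clean.append([m.Ia, m.Ib, m.Ic])
    clean = np.array(clean)
    rng = np.random.default_rng(noise.seed)
    if noise.moment_sigma > 0:
        clean = clean + rng.normal(0.0, noise.moment_sigma, size=clean.shape)
    return clean


def toy_planar_molecule(n_ring_atoms: int, bond_length: float = 1.0,
                        mass: float = 1.0) -> Geometry:
    """Regular planar ring with closed-form moments for oracle tests.

    Ring radius R = L / (2 sin(pi/n)); Ia = Ib = n m R^2 / 2 and
    Ic = n m R^2, so the inertial defect vanishes identically.
    """
    if n_ring_atoms < 3:
        raise InvalidInputError("a ring needs at least three atoms")
    if bond_length <= 0:
        raise InvalidInputError("bond length must be positive")
    R = bond_length / (2.0 * math.sin(math.pi / n_ring_atoms))
    ang = 2.0 * math.pi * np.arange(n_ring_atoms) / n_ring_atoms
    coords = np.column_stack([R * np.cos(ang), R * np.sin(ang),
                              np.zeros(n_ring_atoms)])
    return Geometry(tuple("X" for _ in range(n_ring_atoms)),
                    np.full(n_ring_atoms, float(mass)), coords,
                    tuple(f"X{i}" for i in range(n_ring_atoms)),
                    frame="arbitrary")
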