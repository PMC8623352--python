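"""Forward spectrum prediction and weighted line-list fitting.

Prediction enumerates a-, b- and c-type transitions from the eigenvectors
of the Watson A-reduced Hamiltonian, with line strengths from
molecule-frame dipole matrix elements in the signed-k basis and
intensities from Boltzmann population factors.  Near-planar asymmetric
tops pile high-J R-branch transitions into type-II bands whose spacing
approaches 2C; a band detector measures that spacing.

Fitting is weighted nonlinear least squares of spectroscopic constants
(rotational, quartic/sextic distortion, hyperfine) to mixed-accuracy line
lists, with per-subset rms deviations reported the way spectroscopic
tables quote them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .rotor import (AsymmetricRotor, DistortionSet, InvalidInputError,
                    RotationalConstants, RotationalLevel, ka_kc_ladder)
from .hyperfine import (HyperfineFitParams, QuadrupoleTensor,
                        hyperfine_pattern, tensor_from_fit_params)

__all__ = [
    "StateModel",
    "SpectrumModel",
    "Transition",
    "MeasuredLine",
    "FitResult",
    "predict_spectrum",
    "type2_band_spacing",
    "fit_constants",
]

BOLTZMANN_MHZ_PER_K = 20836.61912  # k_B / h


@dataclass(frozen=True)
class StateModel:
    """One vibronic state: rotational + distortion constants and optional
    hyperfine tensors; weight scales its population relative to others."""

    rc: RotationalConstants
    distortion: DistortionSet = field(default_factory=DistortionSet)
    tensors: tuple[QuadrupoleTensor, ...] = ()
    weight: float = 1.0

    @property
    def label(self) -> str:
        return self.rc.state_label


@dataclass(frozen=True)
class SpectrumModel:
    """Prediction model: states, dipole components (D) and temperature."""

    states: tuple[StateModel, ...]
    mu_a: float = 0.0
    mu_b: float = 0.0
    mu_c: float = 0.0
    temperature: float = 1.0       # K; ~1 K in a supersonic jet
    partition: str = "jet"         # "jet" or "room" (bookkeeping flag)

    @property
    def has_dipole(self) -> bool:
        return any(m != 0.0 for m in (self.mu_a, self.mu_b, self.mu_c))


@dataclass(frozen=True)
class Transition:
    """One predicted rotational transition (hyperfine-free center)."""

    frequency: float       # MHz
    intensity: float       # relative, arbitrary units
    line_strength: float   # S * mu_g^2, Debye^2
    branch: str            # 'a', 'b' or 'c'
    upper: tuple           # (J, Ka, Kc)
    lower: tuple
    state_label: str
    lower_energy: float    # MHz above 0_00


@dataclass(frozen=True)
class MeasuredLine:
    """A measured frequency with uncertainty and quantum assignment.

    hf labels are (I_tot, F) tuples for hyperfine-resolved components,
    None for unresolved lines.  A blend may list several (upper_hf,
    lower_hf) pairs whose intensity-weighted centroid is the model value.
    """

    frequency: float
    uncertainty: float
    upper: tuple           # (J, Ka, Kc)
    lower: tuple
    state_label: str = "ground"
    hf_upper: tuple | None = None
    hf_lower: tuple | None = None
    blend: tuple | None = None   # ((hf_upper, hf_lower), ...)
    source: str = "FTMW"

    def __post_init__(self):
        if self.uncertainty <= 0:
            raise InvalidInputError("line uncertainty must be positive")


@dataclass
class FitResult:
    params: dict
    std_errors: dict
    sigma_fit_khz: dict          # per source tag, plain rms in kHz
    weighted_deviation: float    # sqrt(sum((o-c)/u)^2 / N), unitless
    residuals: pd.DataFrame
    n_lines: int
    converged: bool
    n_evaluations: int
    message: str = ""


# --------------------------------------------------------------------------
# Line strengths
# --------------------------------------------------------------------------

def _cg_q(J_low: int, J_up: int, k: np.ndarray, q: int) -> np.ndarray:
    """Clebsch-Gordan <J_low k; 1 q | J_up k+q> for the dipole operator."""
    j = float(J_low)
    k = k.astype(float)
    if J_up == J_low + 1:
        if q == 0:
            return np.sqrt((j - k + 1) * (j + k + 1) / ((2 * j + 1) * (j + 1)))
        if q == 1:
            return np.sqrt((j + k + 1) * (j + k + 2) / ((2 * j + 1) * (2 * j + 2)))
        if q == -1:
            return np.sqrt((j - k + 1) * (j - k + 2) / ((2 * j + 1) * (2 * j + 2)))
    if J_up == J_low:
        if j == 0:
            return np.zeros_like(k)
        if q == 0:
            return k / np.sqrt(j * (j + 1))
        if q == 1:
            return -np.sqrt((j - k) * (j + k + 1) / (2 * j * (j + 1)))
        if q == -1:
            return np.sqrt((j + k) * (j - k + 1) / (2 * j * (j + 1)))
    raise InvalidInputError("dipole CG defined for J_up in {J_low, J_low+1}")


def _dipole_operator_matrices(J_low: int, J_up: int, mu_a: float, mu_b: float,
                              mu_c: float) -> dict[str, np.ndarray]:
    """Matrices M_g[k_up, k_low] such that amp_g = v_up^T M_g v_low.

    Spherical molecule-frame components in I^r (z=a, x=b, y=c):
    mu_0 = mu_a, mu_{+-1} = (-+ mu_b - i mu_c)/sqrt(2); the b and c parts
    are kept separate (they never connect the same level pair).
    """
    n_lo, n_up = 2 * J_low + 1, 2 * J_up + 1
    klo = np.arange(-J_low, J_low + 1)
    out = {}
    if mu_a:
        M = np.zeros((n_up, n_lo))
        cg = _cg_q(J_low, J_up, klo, 0)
        M[klo + J_up, klo + J_low] = mu_a * cg
        out["a"] = M
    sq2 = math.sqrt(2.0)
    if mu_b:
        M = np.zeros((n_up, n_lo))
        for q, sgn in ((1, -1.0), (-1, 1.0)):
            sel = np.abs(klo + q) <= J_up
            cg = _cg_q(J_low, J_up, klo[sel], q)
            M[klo[sel] + q + J_up, klo[sel] + J_low] += sgn * mu_b / sq2 * cg
        out["b"] = M
    if mu_c:
        # common factor -i/sqrt(2) for both q; modulus is all that matters
        M = np.zeros((n_up, n_lo))
        for q in (1, -1):
            sel = np.abs(klo + q) <= J_up
            cg = _cg_q(J_low, J_up, klo[sel], q)
            M[klo[sel] + q + J_up, klo[sel] + J_low] += mu_c / sq2 * cg
        out["c"] = M
    return out


def predict_spectrum(model: SpectrumModel, f_min: float, f_max: float,
                     J_max: int = 20, min_intensity_ratio: float = 0.0
                     ) -> list[Transition]:
    """Transitions in [f_min, f_max] with relative Boltzmann intensities.

    Selection rules (a-type: ΔKa even / ΔKc odd; b-type: odd/odd;
    c-type: odd/even) emerge from the dipole matrix elements; the branch
    label records which dipole component carries each line.
    """
    if f_min >= f_max:
        raise InvalidInputError("require f_min < f_max")
    if not model.has_dipole:
        return []
    kT = BOLTZMANN_MHZ_PER_K * model.temperature
    out = []
    for st in model.states:
        rotor = AsymmetricRotor(st.rc, st.distortion)
        e000 = rotor.eigensystem(0)[0][0]
        for J_low in range(J_max + 1):
            for J_up in (J_low, J_low + 1):
                if J_up > J_max:
                    continue
                e_lo, v_lo = rotor.eigensystem(J_low)
                e_up, v_up = rotor.eigensystem(J_up)
                mats = _dipole_operator_matrices(J_low, J_up, model.mu_a,
                                                 model.mu_b, model.mu_c)
                lad_lo = ka_kc_ladder(J_low)
                lad_up = ka_kc_ladder(J_up)
                for g, M in mats.items():
                    amp = v_up.T @ M @ v_lo      # (n_up, n_lo)
                    s2 = amp * amp
                    for iu in range(len(lad_up)):
                        for il in range(len(lad_lo)):
                            if J_up == J_low and iu <= il:
                                continue
                            s = s2[iu, il]
                            if s < 1e-12:
                                continue
                            nu = e_up[iu] - e_lo[il]
                            if nu <= 0:
                                continue
                            if not (f_min <= nu <= f_max):
                                continue
                            elow = e_lo[il] - e000
                            inten = (st.weight * nu * s
                                     * (math.exp(-elow / kT)
                                        - math.exp(-(elow + nu) / kT)))
                            out.append(Transition(
                                frequency=nu, intensity=inten,
                                line_strength=s, branch=g,
                                upper=(J_up, *lad_up[iu]),
                                lower=(J_low, *lad_lo[il]),
                                state_label=st.label,
                                lower_energy=elow))
    out.sort(key=lambda t: t.frequency)
    if out and min_intensity_ratio > 0:
        imax = max(t.intensity for t in out)
        out = [t for t in out if t.intensity >= min_intensity_ratio * imax]
    return out


# --------------------------------------------------------------------------
# Type-II bands
# --------------------------------------------------------------------------

def type2_band_spacing(transitions: list[Transition], bin_width: float = 25.0,
                       smooth_mhz: float = 150.0,
                       prominence: float = 0.25) -> float:
    """Mean spacing between successive type-II band centers (MHz).

    Type-II bands are clumps of a-type R-branch transitions (decreasing J,
    increasing Ka at nearly constant frequency).  The detector bins the
    R-branch intensity into a profile, smooths it, locates band centers as
    prominent local maxima, and returns the mean center-to-center spacing,
    which approaches 2C for a near-planar asymmetric top.
    """
    from scipy import ndimage, signal
    sel = [t for t in transitions
           if t.branch == "a" and t.upper[0] == t.lower[0] + 1]
    if not sel:
        sel = [t for t in transitions if t.upper[0] == t.lower[0] + 1]
    if len(sel) < 2:
        raise InvalidInputError("not enough R-branch transitions for bands")
    freqs = np.array([t.frequency for t in sel])
    inten = np.array([t.intensity for t in sel])
    bins = np.arange(freqs.min() - bin_width, freqs.max() + 2 * bin_width,
                     bin_width)
    prof, _ = np.histogram(freqs, bins=bins, weights=inten)
    prof = ndimage.gaussian_filter1d(prof, sigma=max(smooth_mhz / bin_width, 1.0))
    peaks, _ = signal.find_peaks(prof, prominence=prominence * prof.max())
    if len(peaks) < 2:
        raise InvalidInputError("fewer than two bands detected in window")
    centers = bins[peaks] + 0.5 * bin_width
    return float((centers[-1] - centers[0]) / (len(centers) - 1))


# --------------------------------------------------------------------------
# Weighted global least-squares fit
# --------------------------------------------------------------------------

_RC_NAMES = ("A", "B", "C")
_DIST_NAMES = {"DJ": "delta_J", "DJK": "delta_JK", "DK": "delta_K",
               "dJ": "small_delta_J", "dK": "small_delta_K", "HK": "H_K"}
_HF_NAMES = {"chi32aa": "three_halves_chi_aa",
             "chibbcc4": "quarter_chi_bb_minus_cc",
             "chiab": "chi_ab"}


@dataclass
class FitConfig:
    max_iter: int = 200
    rel_tol: float = 1e-10


class ConstantsModel:
    """Mutable parameter container for fitting one or more states.

    Parameter keys: "<state>:A", "<state>:DJ", ...,
    "<state>:<nucleus>:chi32aa" etc.  Hyperfine tensors are carried as
    fit-parameter sets (the combinations actually varied in the fit).
    """

    def __init__(self, states: dict[str, dict]):
        # states[label] = {"rc": RotationalConstants, "distortion":
        #   DistortionSet, "tensors": [HyperfineFitParams, ...]}
        self.states = {}
        for label, d in states.items():
            self.states[label] = {
                "rc": d["rc"],
                "distortion": d.get("distortion", DistortionSet()),
                "tensors": list(d.get("tensors", [])),
            }

    def copy(self) -> "ConstantsModel":
        return ConstantsModel({
            label: {"rc": d["rc"], "distortion": d["distortion"],
                    "tensors": list(d["tensors"])}
            for label, d in self.states.items()})

    def get(self, key: str) -> float:
        parts = key.split(":")
        d = self.states[parts[0]]
        if len(parts) == 2:
            name = parts[1]
            if name in _RC_NAMES:
                return getattr(d["rc"], name)
            return getattr(d["distortion"], _DIST_NAMES[name])
        nuc, name = parts[1], parts[2]
        for t in d["tensors"]:
            if t.nucleus_label == nuc:
                return getattr(t, _HF_NAMES[name])
        raise KeyError(key)

    def set(self, key: str, value: float) -> None:
        parts = key.split(":")
        d = self.states[parts[0]]
        if len(parts) == 2:
            name = parts[1]
            if name in _RC_NAMES:
                d["rc"] = replace(d["rc"], **{name: value})
            else:
                d["distortion"] = replace(d["distortion"],
                                          **{_DIST_NAMES[name]: value})
            return
        nuc, name = parts[1], parts[2]
        for i, t in enumerate(d["tensors"]):
            if t.nucleus_label == nuc:
                d["tensors"][i] = replace(t, **{_HF_NAMES[name]: value})
                return
        raise KeyError(key)

    def rotor(self, label: str) -> AsymmetricRotor:
        d = self.states[label]
        return AsymmetricRotor(d["rc"], d["distortion"])

    def quad_tensors(self, label: str) -> list[QuadrupoleTensor]:
        return [tensor_from_fit_params(p) for p in self.states[label]["tensors"]]


def _match_component(components, hf_upper, hf_lower):
    """Component whose (I_tot, F) labels best match the assignment.

    F labels are exact; within near-degenerate blocks the I_tot
    composition can mix, so among components with the right F pair the
    one with the largest weight on the assigned I_tot values is taken.
    """
    itu, fu = hf_upper
    itl, fl = hf_lower
    for c in components:
        if (c.upper[3], c.upper[4]) == (itu, fu) and \
                (c.lower[3], c.lower[4]) == (itl, fl):
            return c
    best, best_w = None, -1.0
    for c in components:
        if c.upper[4] != fu or c.lower[4] != fl:
            continue
        wu = dict(c.upper_weights).get(itu, 1.0 if c.upper[3] == itu else 0.0)
        wl = dict(c.lower_weights).get(itl, 1.0 if c.lower[3] == itl else 0.0)
        if wu * wl > best_w:
            best, best_w = c, wu * wl
    if best is None:
        raise InvalidInputError(
            f"no hyperfine component with labels {hf_upper} <- {hf_lower}")
    return best


def _predicted_frequency(line: MeasuredLine, model: ConstantsModel,
                         rotor_cache: dict, pattern_cache: dict) -> float:
    label = line.state_label
    if label not in rotor_cache:
        rotor_cache[label] = model.rotor(label)
    rotor = rotor_cache[label]
    ju, kau, kcu = line.upper
    jl, kal, kcl = line.lower
    nu0 = rotor.level_energy(ju, kau, kcu) - rotor.level_energy(jl, kal, kcl)
    needs_hf = (line.hf_upper is not None) or (line.blend is not None)
    if not needs_hf:
        return nu0
    key = (label, line.upper, line.lower)
    if key not in pattern_cache:
        tensors = model.quad_tensors(label)
        up = RotationalLevel(ju, kau, kcu, 0.0, label)
        lo = RotationalLevel(jl, kal, kcl, 0.0, label)
        pattern_cache[key] = hyperfine_pattern(up, lo, tensors, rotor)
    comps = pattern_cache[key]
    if line.blend is not None:
        sel = [_match_component(comps, u, l) for u, l in line.blend]
        w = sum(c.intensity for c in sel)
        return nu0 + sum(c.intensity * c.offset for c in sel) / w
    c = _match_component(comps, line.hf_upper, line.hf_lower)
    return nu0 + c.offset


def fit_constants(lines: list[MeasuredLine], model: ConstantsModel,
                  free: list[str], config: FitConfig | None = None
                  ) -> FitResult:
    """Weighted least-squares fit of the free constants to a line list.

    Minimizes sum(((obs - calc)/u)^2).  Standard errors come from the
    unscaled weighted covariance (J^T W J)^-1, so they track the supplied
    measurement uncertainties directly.  sigma_fit is reported per source
    tag as the plain rms of (obs - calc) in kHz.
    """
    if not lines:
        raise InvalidInputError("empty line list")
    config = config or FitConfig()
    work = model.copy()

    def residuals(x: np.ndarray) -> np.ndarray:
        for key, val in zip(free, x):
            work.set(key, val)
        rotor_cache: dict = {}
        pattern_cache: dict = {}
        return np.array([
            (line.frequency - _predicted_frequency(line, work, rotor_cache,
                                                   pattern_cache))
            / line.uncertainty
            for line in lines])

    if free:
        x0 = np.array([model.get(k) for k in free])
        scale = np.maximum(np.abs(x0), 1e-6)
        res = least_squares(residuals, x0, method="lm",
                            xtol=config.rel_tol, ftol=config.rel_tol,
                            gtol=1e-14, x_scale=scale,
                            max_nfev=config.max_iter * (len(free) + 1))
        if not res.success:
            raise RuntimeError(f"fit did not converge: {res.message}")
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            deficient = [free[i] for i in range(len(free))
                         if jtj[i, i] < 1e-20]
            raise InvalidInputError(
                f"singular normal equations; unconstrained: {deficient}")
        std = dict(zip(free, np.sqrt(np.diag(cov))))
        values = dict(zip(free, res.x))
        converged, nfev, msg = res.success, res.nfev, res.message
        r_weighted = res.fun
    else:
        values, std = {}, {}
        converged, nfev, msg = True, 1, "all parameters fixed"
        r_weighted = residuals(np.array([]))

    resid_mhz = r_weighted * np.array([l.uncertainty for l in lines])
    table = pd.DataFrame({
        "state": [l.state_label for l in lines],
        "source": [l.source for l in lines],
        "obs_mhz": [l.frequency for l in lines],
        "obs_minus_calc_mhz": resid_mhz,
        "uncertainty_mhz": [l.uncertainty for l in lines],
    })
    sigma = {src: float(np.sqrt(np.mean(g["obs_minus_calc_mhz"]**2))) * 1e3
             for src, g in table.groupby("source")}
    wdev = float(np.sqrt(np.mean(r_weighted**2)))
    return FitResult(params=values, std_errors=std, sigma_fit_khz=sigma,
                     weighted_deviation=wdev, residuals=table,
                     n_lines=len(lines), converged=converged,
                     n_evaluations=nfev, message=msg)
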