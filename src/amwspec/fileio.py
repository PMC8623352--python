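"""Readers and writers for the plain-text formats used around the fits.

lin-style measurement files: quantum numbers first, then frequency and
uncertainty, in fixed whitespace-separated columns with an explicit
column map (no format sniffing).  cat-style prediction files: frequency,
base-10 log intensity and quantum labels.  Spectroscopic constants
travel as YAML key-value files mirroring the usual table naming (A, B, C
in MHz; DJ, DJK, DK, dJ, dK in kHz; HK in Hz; hyperfine combinations in
MHz).
"""

from __future__ import annotations

import math

import yaml

from .hyperfine import HyperfineFitParams
from .rotor import DistortionSet, InvalidInputError, RotationalConstants
from .spectra import MeasuredLine, Transition

__all__ = [
    "DEFAULT_LIN_COLUMNS",
    "read_lin",
    "write_lin",
    "write_cat",
    "read_constants_config",
    "write_constants_config",
]

#: Column order of the lin dialect: six rotational quantum numbers
#: (upper then lower), frequency (MHz), uncertainty (MHz), then optional
#: trailing columns.
DEFAULT_LIN_COLUMNS = ("J_up", "Ka_up", "Kc_up", "J_lo", "Ka_lo", "Kc_lo",
                       "frequency", "uncertainty", "source", "state")


def read_lin(path, columns: tuple[str, ...] = DEFAULT_LIN_COLUMNS,
             default_state: str = "ground",
             default_source: str = "FTMW") -> list[MeasuredLine]:
    """Parse a lin-style file; '#' starts a comment, blank lines skipped."""
    required = {"J_up", "Ka_up", "Kc_up", "J_lo", "Ka_lo", "Kc_lo",
                "frequency", "uncertainty"}
    if not required <= set(columns):
        raise InvalidInputError(f"column map must include {sorted(required)}")
    lines = []
    with open(path) as fh:
        for raw in fh:
            body = raw.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) < len(required):
                raise InvalidInputError(f"short line in {path!s}: {raw!r}")
            rec = dict(zip(columns, parts))
            lines.append(MeasuredLine(
                frequency=float(rec["frequency"]),
                uncertainty=float(rec["uncertainty"]),
                upper=(int(rec["J_up"]), int(rec["Ka_up"]), int(rec["Kc_up"])),
                lower=(int(rec["J_lo"]), int(rec["Ka_lo"]), int(rec["Kc_lo"])),
                state_label=rec.get("state", default_state),
                source=rec.get("source", default_source)))
    return lines


def write_lin(lines: list[MeasuredLine], path) -> None:
    with open(path, "w") as fh:
        fh.write("# J' Ka' Kc'  J  Ka Kc   frequency/MHz  unc/MHz  source  state\n")
        for l in lines:
            fh.write(f"{l.upper[0]:3d} {l.upper[1]:3d} {l.upper[2]:3d} "
                     f"{l.lower[0]:3d} {l.lower[1]:3d} {l.lower[2]:3d} "
                     f"{l.frequency:15.6f} {l.uncertainty:9.6f} "
                     f"{l.source:6s} {l.state_label}\n")


def write_cat(transitions: list[Transition], path) -> None:
    """Write a cat-style prediction: frequency, log10 intensity, labels."""
    imax = max((t.intensity for t in transitions), default=1.0)
    with open(path, "w") as fh:
        fh.write("# frequency/MHz  log10(I/Imax)  J' Ka' Kc'  J Ka Kc  "
                 "branch  state\n")
        for t in transitions:
            logi = math.log10(max(t.intensity / imax, 1e-30))
            fh.write(f"{t.frequency:15.4f} {logi:8.3f} "
                     f"{t.upper[0]:3d} {t.upper[1]:3d} {t.upper[2]:3d} "
                     f"{t.lower[0]:3d} {t.lower[1]:3d} {t.lower[2]:3d} "
                     f"  {t.branch}   {t.state_label}\n")


_DIST_IO = {"DJ": "delta_J", "DJK": "delta_JK", "DK": "delta_K",
            "dJ": "small_delta_J", "dK": "small_delta_K", "HK": "H_K"}


def read_constants_config(path) -> dict:
    """Read one state's constants from YAML.

    Returns {"rc": RotationalConstants, "distortion": DistortionSet,
    "tensors": [HyperfineFitParams, ...]}.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    rc = RotationalConstants(data["A"], data["B"], data["C"],
                             state_label=data.get("state", "ground"))
    dist = DistortionSet(**{_DIST_IO[k]: data[k] for k in _DIST_IO
                            if k in data})
    tensors = []
    for nuc, d in (data.get("hyperfine") or {}).items():
        tensors.append(HyperfineFitParams(
            three_halves_chi_aa=d["chi32aa"],
            quarter_chi_bb_minus_cc=d["chibbcc4"],
            chi_ab=d.get("chiab", 0.0), nucleus_label=nuc))
    return {"rc": rc, "distortion": dist, "tensors": tensors}


def write_constants_config(path, rc: RotationalConstants,
                           dist: DistortionSet | None = None,
                           tensors: list[HyperfineFitParams] = ()) -> None:
    data = {"state": rc.state_label, "A": rc.A, "B": rc.B, "C": rc.C}
    if dist is not None:
        for k, attr in _DIST_IO.items():
            val = getattr(dist, attr)
            if val != 0.0:
                data[k] = val
    if tensors:
        data["hyperfine"] = {
            t.nucleus_label: {"chi32aa": t.three_halves_chi_aa,
                              "chibbcc4": t.quarter_chi_bb_minus_cc,
                              **({"chiab": t.chi_ab} if t.chi_ab else {})}
            for t in tensors}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
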