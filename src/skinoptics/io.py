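"""Readers and writers binding the pipeline stages together.

Spectra travel as CSV (wavelength_nm, Rd, Tt[, sd_Rd, sd_Tt]); label volumes
and fluence fields as raw little-endian binary volumes with a JSON sidecar
(dims, voxel pitch, label table) following the mcxyz file convention;
results as versioned JSON reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .optics_core import MeasuredSpectrum, OpticalProperties
from .skin_voxel import BeamSpec, FluenceField, VoxelGrid

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_grid",
    "write_grid",
    "read_fluence",
    "write_fluence",
    "write_report",
]

REPORT_SCHEMA_VERSION = 1


class SpectrumParseError(ValueError):
    """Malformed spectrum file; the message names the offending row."""


def read_spectrum(path: str | Path, thickness_mm: float | None = None) -> MeasuredSpectrum:
    """Read a Rd/Tt spectrum CSV.

    Required columns: wavelength_nm, Rd, Tt; optional: sd_Rd, sd_Tt.  The
    slab thickness is taken from a ``# thickness_mm = X`` header comment if
    present, else from the ``thickness_mm`` argument.
    """
    path = Path(path)
    header_thickness = None
    with path.open() as fh:
        for line in fh:
            if line.startswith("#") and "thickness_mm" in line:
                header_thickness = float(line.split("=")[1])
            elif not line.startswith("#"):
                break
    frame = pd.read_csv(path, comment="#")
    required = {"wavelength_nm", "Rd", "Tt"}
    missing = required - set(frame.columns)
    if missing:
        raise SpectrumParseError(f"{path}: missing columns {sorted(missing)}")
    wl = frame["wavelength_nm"].to_numpy(dtype=float)
    rd = frame["Rd"].to_numpy(dtype=float)
    tt = frame["Tt"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        row = int(np.nonzero(np.diff(wl) <= 0)[0][0]) + 2
        raise SpectrumParseError(f"{path}: wavelengths not strictly increasing at line {row}")
    bad = np.nonzero((rd < 0) | (rd > 1) | (tt < 0) | (tt > 1) | (rd + tt > 1))[0]
    if bad.size:
        raise SpectrumParseError(
            f"{path}: Rd/Tt out of range (0 <= Rd, Tt, Rd+Tt <= 1) at line {bad[0] + 2}"
        )
    thickness = header_thickness if header_thickness is not None else thickness_mm
    if thickness is None:
        raise SpectrumParseError(f"{path}: slab thickness not given (header or argument)")
    kwargs = {}
    if "sd_Rd" in frame.columns:
        kwargs["sd_rd"] = frame["sd_Rd"].to_numpy(dtype=float)
    if "sd_Tt" in frame.columns:
        kwargs["sd_tt"] = frame["sd_Tt"].to_numpy(dtype=float)
    return MeasuredSpectrum(wavelength_nm=wl, rd=rd, tt=tt, thickness_mm=thickness, **kwargs)


def write_spectrum(spectrum: MeasuredSpectrum, path: str | Path) -> None:
    """Write a spectrum CSV (round-trips bit-exactly through read_spectrum)."""
    path = Path(path)
    cols = {"wavelength_nm": spectrum.wavelength_nm, "Rd": spectrum.rd, "Tt": spectrum.tt}
    if spectrum.sd_rd is not None:
        cols["sd_Rd"] = spectrum.sd_rd
    if spectrum.sd_tt is not None:
        cols["sd_Tt"] = spectrum.sd_tt
    with path.open("w") as fh:
        fh.write(f"# thickness_mm = {spectrum.thickness_mm!r}\n")
        # pandas' default float formatting is shortest-roundtrip repr
        pd.DataFrame(cols).to_csv(fh, index=False)


def write_grid(grid: VoxelGrid, directory: str | Path) -> None:
    """Persist a label volume as raw uint8 + JSON sidecar (mcxyz convention)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid.labels.tofile(directory / "labels.u8")
    sidecar = {
        "dims": list(grid.shape),
        "pitch_mm": grid.pitch_mm,
        "order": "C",
        "dtype": "uint8",
        "layer_boundaries_mm": grid.layer_boundaries_mm,
        "seed": grid.seed,
        "labels": {
            str(lab): {
                "mu_a": p.mu_a, "mu_s": p.mu_s, "g": p.g, "n": p.n,
            }
            for lab, p in grid.properties.items()
        },
    }
    (directory / "grid.json").write_text(json.dumps(sidecar, indent=1))


def read_grid(directory: str | Path) -> VoxelGrid:
    directory = Path(directory)
    sidecar = json.loads((directory / "grid.json").read_text())
    dims = tuple(sidecar["dims"])
    labels = np.fromfile(directory / "labels.u8", dtype=np.uint8).reshape(dims)
    properties = {
        int(lab): OpticalProperties(**vals) for lab, vals in sidecar["labels"].items()
    }
    lb = sidecar.get("layer_boundaries_mm")
    return VoxelGrid(
        labels=labels,
        pitch_mm=sidecar["pitch_mm"],
        properties=properties,
        layer_boundaries_mm=tuple(lb) if lb else None,
        seed=sidecar.get("seed"),
    )


def write_fluence(field: FluenceField, directory: str | Path) -> None:
    """Persist a fluence field as raw float32 + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    field.fluence.astype(np.float32).tofile(directory / "fluence.f32")
    sidecar = {
        "dims": list(field.shape),
        "pitch_mm": field.pitch_mm,
        "order": "C",
        "dtype": "float32",
        "beam_diameter_mm": field.beam.diameter_mm,
        "escaped": field.escaped,
        "absorbed": field.absorbed,
        "n_photons": field.n_photons,
        "seed": field.seed,
    }
    (directory / "fluence.json").write_text(json.dumps(sidecar, indent=1))


def read_fluence(directory: str | Path) -> FluenceField:
    directory = Path(directory)
    sidecar = json.loads((directory / "fluence.json").read_text())
    dims = tuple(sidecar["dims"])
    fluence = np.fromfile(directory / "fluence.f32", dtype=np.float32).reshape(dims)
    return FluenceField(
        fluence=fluence.astype(np.float64),
        pitch_mm=sidecar["pitch_mm"],
        beam=BeamSpec(diameter_mm=sidecar["beam_diameter_mm"]),
        escaped=sidecar["escaped"],
        absorbed=sidecar["absorbed"],
        n_photons=sidecar["n_photons"],
        seed=sidecar["seed"],
    )


def write_report(payload: dict, path: str | Path) -> None:
    """Write a versioned JSON report; numpy scalars/arrays are converted."""
    def convert(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating, np.bool_)):
            return obj.item()
        raise TypeError(f"unserializable object of type {type(obj)}")

    payload = {"schema_version": REPORT_SCHEMA_VERSION, **payload}
    Path(path).write_text(json.dumps(payload, indent=1, default=convert))
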