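"""Domain types, unit conventions, and packaged reference tables.

Conventions used throughout the package:

* lengths in **mm**, interaction coefficients in **mm⁻¹**; vessel and voxel
  dimensions quoted in μm are converted at the boundary of the API;
* ``mu_a`` absorption coefficient, ``mu_s`` scattering coefficient,
  ``g`` scattering anisotropy (mean cosine of the single-scattering
  deflection), ``mu_s_prime = mu_s * (1 - g)`` reduced scattering
  coefficient, ``n`` refractive index;
* diffuse reflectance ``Rd`` and total transmittance ``Tt`` are fractions of
  the incident power; the specular (Fresnel) reflection of the collimated
  beam is reported separately from ``Rd``.

The packaged CSV tables hold the measured layer coefficients of Asian
epidermis, dermis and subcutaneous fat at nine clinical laser wavelengths,
whole-blood coefficients at 96% oxygen saturation, and the dermal-vasculature
geometry of the layered skin model.  They are checksum-verified on load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OpticalProperties",
    "MeasuredSpectrum",
    "TissueOpticsTable",
    "BloodTable",
    "VesselParams",
    "PlexusSpec",
    "mus_from_musp",
    "load_paper_tables",
    "N_EPIDERMIS",
    "N_DERMIS",
    "N_FAT",
    "N_GLASS",
    "DEFAULT_G",
    "MU_A_FLOOR",
    "TABLE_WAVELENGTHS_NM",
]

#: Fixed refractive indices of the three skin layers (valid around 633 nm but
#: applied at all wavelengths, matching the layered-model simplification).
N_EPIDERMIS = 1.34
N_DERMIS = 1.39
N_FAT = 1.44
#: Standard microscope slide glass.
N_GLASS = 1.52
#: Default scattering anisotropy assumed for soft tissue.
DEFAULT_G = 0.9
#: Floor applied when a mean − 1 SD absorption coefficient would be ≤ 0.
MU_A_FLOOR = 1e-4
#: The nine clinical laser wavelengths of the packaged tissue table (nm).
TABLE_WAVELENGTHS_NM = (405, 532, 595, 632, 694, 755, 800, 980, 1064)


def mus_from_musp(mu_s_prime: float, g: float) -> float:
    """Scattering coefficient μs from the reduced coefficient μs′ = μs(1−g).

    Parameters
    ----------
    mu_s_prime : float
        Reduced scattering coefficient (mm⁻¹), ≥ 0.
    g : float
        Scattering anisotropy, must satisfy −1 < g < 1.
    """
    if not -1.0 < g < 1.0:
        raise ValueError(f"anisotropy g={g!r} must lie in (-1, 1)")
    if mu_s_prime < 0:
        raise ValueError(f"mu_s_prime={mu_s_prime!r} must be non-negative")
    return mu_s_prime / (1.0 - g)


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of one homogeneous medium at one wavelength.

    Attributes
    ----------
    mu_a, mu_s : float
        Absorption / scattering coefficients (mm⁻¹).
    g : float
        Scattering anisotropy in (−1, 1).
    n : float
        Refractive index, ≥ 1.
    """

    mu_a: float
    mu_s: float
    g: float = DEFAULT_G
    n: float = 1.4

    def __post_init__(self) -> None:
        if not np.isfinite([self.mu_a, self.mu_s, self.g, self.n]).all():
            raise ValueError("optical properties must be finite")
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"anisotropy g={self.g!r} must lie in (-1, 1)")
        if self.n < 1.0:
            raise ValueError(f"refractive index n={self.n!r} must be >= 1")

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient μs(1−g) in mm⁻¹."""
        return self.mu_s * (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient μa + μs in mm⁻¹."""
        return self.mu_a + self.mu_s

    @classmethod
    def from_reduced(
        cls, mu_a: float, mu_s_prime: float, g: float = DEFAULT_G, n: float = 1.4
    ) -> "OpticalProperties":
        """Build from (μa, μs′) using the similarity relation μs = μs′/(1−g)."""
        return cls(mu_a=mu_a, mu_s=mus_from_musp(mu_s_prime, g), g=g, n=n)


@dataclass(frozen=True)
class MeasuredSpectrum:
    """Per-wavelength diffuse reflectance / total transmittance of one slab.

    ``Rd`` and ``Tt`` are fractions in [0, 1] with ``Rd + Tt <= 1`` at every
    wavelength; ``sd_rd``/``sd_tt`` are 1-SD uncertainties on the same scale.
    ``thickness_mm`` is the tissue-slab thickness (excluding mounting glass).
    """

    wavelength_nm: np.ndarray
    rd: np.ndarray
    tt: np.ndarray
    thickness_mm: float
    sd_rd: np.ndarray | None = None
    sd_tt: np.ndarray | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        rd = np.asarray(self.rd, dtype=float)
        tt = np.asarray(self.tt, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "rd", rd)
        object.__setattr__(self, "tt", tt)
        if not (wl.shape == rd.shape == tt.shape) or wl.ndim != 1:
            raise ValueError("wavelength, Rd and Tt must be 1-D arrays of equal length")
        if wl.size and np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any((rd < 0) | (rd > 1)) or np.any((tt < 0) | (tt > 1)):
            raise ValueError("Rd and Tt must lie in [0, 1]")
        bad = np.nonzero(rd + tt > 1.0 + 1e-12)[0]
        if bad.size:
            raise ValueError(f"Rd + Tt exceeds 1 at row(s) {bad.tolist()}")
        if self.thickness_mm <= 0:
            raise ValueError("slab thickness must be positive")
        for name in ("sd_rd", "sd_tt"):
            sd = getattr(self, name)
            if sd is not None:
                sd = np.asarray(sd, dtype=float)
                object.__setattr__(self, name, sd)
                if sd.shape != wl.shape or np.any(sd < 0):
                    raise ValueError(f"{name} must be non-negative and match wavelengths")

    def __len__(self) -> int:
        return self.wavelength_nm.size


class TissueOpticsTable:
    """Measured (μa, μs′) mean ± 1 SD per skin layer at nine wavelengths.

    Thin wrapper over a tidy DataFrame with columns
    (tissue, wavelength_nm, mu_a_mean, mu_a_sd, mu_s_prime_mean, mu_s_prime_sd).
    """

    TISSUES = ("epidermis", "dermis", "subcutaneous_fat")

    def __init__(self, frame: pd.DataFrame):
        required = {
            "tissue", "wavelength_nm", "mu_a_mean", "mu_a_sd",
            "mu_s_prime_mean", "mu_s_prime_sd",
        }
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"tissue table missing columns {sorted(missing)}")
        wls = tuple(sorted(frame["wavelength_nm"].unique()))
        if wls != tuple(float(w) for w in TABLE_WAVELENGTHS_NM):
            raise ValueError("tissue table must cover exactly the nine tabulated wavelengths")
        if set(frame["tissue"].unique()) != set(self.TISSUES):
            raise ValueError("tissue table must cover epidermis, dermis, subcutaneous_fat")
        if (frame[["mu_a_mean", "mu_s_prime_mean"]] <= 0).any().any():
            raise ValueError("mean coefficients must be positive")
        if (frame[["mu_a_sd", "mu_s_prime_sd"]] < 0).any().any():
            raise ValueError("standard deviations must be non-negative")
        if (frame["mu_s_prime_mean"] - frame["mu_s_prime_sd"] <= 0).any():
            raise ValueError("mean - 1 SD must stay positive for every mu_s_prime entry")
        self.frame = frame.reset_index(drop=True)

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return np.asarray(TABLE_WAVELENGTHS_NM, dtype=float)

    def lookup(self, tissue: str, wavelength_nm: float) -> pd.Series:
        sel = self.frame[
            (self.frame["tissue"] == tissue)
            & (self.frame["wavelength_nm"] == wavelength_nm)
        ]
        if len(sel) != 1:
            raise KeyError(f"no entry for {tissue!r} at {wavelength_nm} nm")
        return sel.iloc[0]

    def coefficients(
        self, tissue: str, wavelength_nm: float, sd_offset: float = 0.0
    ) -> tuple[float, float, bool]:
        """(μa, μs′) at ``mean + sd_offset·SD``; μa clamped at ``MU_A_FLOOR``.

        Returns the pair and a flag that is True when the absorption
        coefficient had to be clamped to the floor.
        """
        row = self.lookup(tissue, wavelength_nm)
        mu_a = row["mu_a_mean"] + sd_offset * row["mu_a_sd"]
        mu_sp = row["mu_s_prime_mean"] + sd_offset * row["mu_s_prime_sd"]
        clamped = False
        if mu_a <= MU_A_FLOOR:
            mu_a = MU_A_FLOOR
            clamped = True
        if mu_sp <= 0:
            raise ValueError(f"non-positive mu_s_prime for {tissue} at {wavelength_nm} nm")
        return float(mu_a), float(mu_sp), clamped


class BloodTable:
    """Whole-blood μa and μs′ (mm⁻¹) at the nine tabulated wavelengths."""

    def __init__(self, frame: pd.DataFrame, oxygen_saturation: float = 0.96):
        required = {"wavelength_nm", "mu_a", "mu_s_prime"}
        if required - set(frame.columns):
            raise ValueError("blood table missing required columns")
        self.frame = frame.reset_index(drop=True)
        self.oxygen_saturation = oxygen_saturation

    def lookup(self, wavelength_nm: float) -> tuple[float, float]:
        sel = self.frame[self.frame["wavelength_nm"] == wavelength_nm]
        if len(sel) != 1:
            raise KeyError(f"no blood entry at {wavelength_nm} nm")
        return float(sel["mu_a"].iloc[0]), float(sel["mu_s_prime"].iloc[0])

    def interpolate(self, wavelength_nm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linear-in-λ interpolation between the nine anchor wavelengths."""
        wl = np.asarray(wavelength_nm, dtype=float)
        anchors = self.frame["wavelength_nm"].to_numpy(dtype=float)
        mu_a = np.interp(wl, anchors, self.frame["mu_a"].to_numpy(dtype=float))
        mu_sp = np.interp(wl, anchors, self.frame["mu_s_prime"].to_numpy(dtype=float))
        return mu_a, mu_sp


@dataclass(frozen=True)
class PlexusSpec:
    """One dermal vessel plexus: depth, in-band blood fraction, diameter."""

    center_depth_um: float
    volume_fraction_pct: float
    diameter_um: float

    def __post_init__(self) -> None:
        if not 0 < self.volume_fraction_pct <= 100:
            raise ValueError("volume fraction must lie in (0, 100]")
        if self.diameter_um <= 0:
            raise ValueError("vessel diameter must be positive")


@dataclass(frozen=True)
class VesselParams:
    """Dermal vasculature geometry of the layered skin model."""

    capillary: PlexusSpec
    upper: PlexusSpec
    deep: PlexusSpec
    capillary_band_thickness_um: float = 150.0

    def __post_init__(self) -> None:
        for name in ("capillary", "upper", "deep"):
            plexus: PlexusSpec = getattr(self, name)
            if plexus.center_depth_um <= 0:
                raise ValueError(f"{name} plexus depth must be positive")


def _data_path(name: str):
    return resources.files("skinoptics.data").joinpath(name)


def _verify_checksum(name: str, meta: Mapping) -> None:
    digest = hashlib.sha256(_data_path(name).read_bytes()).hexdigest()
    if digest != meta[name]["sha256"]:
        raise RuntimeError(
            f"packaged table {name} is corrupted (checksum mismatch); reinstall the package"
        )


def load_paper_tables() -> tuple[TissueOpticsTable, BloodTable, VesselParams]:
    """Load the packaged layer, blood and vessel tables (checksum-verified)."""
    with _data_path("metadata.json").open() as fh:
        meta = json.load(fh)

    name = "tissue_optical_properties.csv"
    _verify_checksum(name, meta)
    tissue = TissueOpticsTable(pd.read_csv(_data_path(name)))

    name = "whole_blood_optical_properties.csv"
    _verify_checksum(name, meta)
    blood = BloodTable(
        pd.read_csv(_data_path(name)),
        oxygen_saturation=meta[name]["oxygen_saturation"],
    )

    name = "vessel_parameters.csv"
    _verify_checksum(name, meta)
    vframe = pd.read_csv(_data_path(name)).set_index("plexus")
    plexuses = {
        key: PlexusSpec(
            center_depth_um=float(vframe.loc[key, "center_depth_um"]),
            volume_fraction_pct=float(vframe.loc[key, "volume_fraction_pct"]),
            diameter_um=float(vframe.loc[key, "diameter_um"]),
        )
        for key in ("capillary", "upper", "deep")
    }
    vessels = VesselParams(
        capillary=plexuses["capillary"],
        upper=plexuses["upper"],
        deep=plexuses["deep"],
        capillary_band_thickness_um=float(meta[name]["capillary_band_thickness_um"]),
    )
    return tissue, blood, vessels
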