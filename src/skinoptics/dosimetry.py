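"""Optical penetration depth δ and energy deposition S from fluence fields.

δ is the depth at which the fluence inside the tissue, normalized to the
incident irradiance at the surface, first falls to 1/e (36.8%) and stays
below; it is read off the on-axis depth profile with linear interpolation in
log-fluence between the bracketing voxel centres.  Uncertainty bounds follow
from the ±1 SD property sets of the measured layer coefficients: the maximum
δ from the (mean − 1 SD) set, the minimum from (mean + 1 SD), with the
absorption floor applied (and flagged) where mean − SD would be non-positive.

S is the locally absorbed power density per unit incident irradiance:
``S[v] = μa(label[v]) · F[v]`` (mm⁻¹), the heat source of photothermal
modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics_core import (
    DEFAULT_G,
    BloodTable,
    OpticalProperties,
    TissueOpticsTable,
    VesselParams,
)
from .skin_voxel import BeamSpec, FluenceField, VoxelGrid, build_skin_model, simulate_voxel

__all__ = [
    "DosimetryResult",
    "on_axis_profile",
    "penetration_depth",
    "energy_deposition",
    "s_profile",
    "delta_bounds",
    "layer_properties_at",
]

#: layer refractive indices reused when building voxel property sets
_LAYER_N = {"epidermis": 1.34, "dermis": 1.39, "subcutaneous_fat": 1.44}


@dataclass
class DosimetryResult:
    """Penetration depth with ±1 SD bounds and on-axis energy deposition."""

    wavelength_nm: float
    beam_mm: float
    delta_mm: float
    delta_min_mm: float | None = None
    delta_max_mm: float | None = None
    z_mm: np.ndarray | None = None
    s_profile: np.ndarray | None = None
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.delta_min_mm is not None and self.delta_max_mm is not None:
            if not self.delta_min_mm <= self.delta_mm <= self.delta_max_mm:
                raise AssertionError("delta bounds must bracket the mean-value delta")


def on_axis_profile(field: FluenceField, window: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Depth profile of the fluence along the beam axis.

    Averages the central ``window × window`` voxel columns (window = 1 for the
    strict single-column reading); returns (z at voxel centres in mm, F(z)).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    nx, ny, _ = field.shape
    half = window // 2
    cx, cy = nx // 2, ny // 2
    cols = field.fluence[cx - half : cx + half + 1, cy - half : cy + half + 1, :]
    profile = cols.mean(axis=(0, 1))
    z = (np.arange(field.shape[2]) + 0.5) * field.pitch_mm
    return z, profile


def penetration_depth(field: FluenceField, window: int = 3) -> float:
    """Depth (mm) at which the on-axis fluence first falls below 1/e for good.

    The crossing must persist for the following voxel; the depth is linearly
    interpolated in log-fluence between the bracketing voxel centres.
    Raises ``ValueError`` if the profile never falls below 1/e inside the
    grid ("penetration exceeds grid depth").
    """
    z, profile = on_axis_profile(field, window=window)
    threshold = np.exp(-1.0)
    below = profile < threshold
    # shallowest index below threshold whose successor is also below
    idx = None
    for i in range(below.size - 1):
        if below[i] and below[i + 1]:
            idx = i
            break
    if idx is None:
        raise ValueError("penetration exceeds grid depth: fluence never falls below 1/e")
    if idx == 0:
        return float(z[0])
    f_hi, f_lo = profile[idx - 1], profile[idx]
    if f_hi <= 0 or f_lo <= 0 or f_hi <= f_lo:
        return float(z[idx])
    # linear in log-fluence between bracketing voxel centres
    t = (np.log(f_hi) - (-1.0)) / (np.log(f_hi) - np.log(f_lo))
    return float(z[idx - 1] + t * (z[idx] - z[idx - 1]))


def energy_deposition(field: FluenceField, grid: VoxelGrid) -> np.ndarray:
    """Per-voxel energy deposition S = μa · F (mm⁻¹ per unit incident irradiance)."""
    if field.shape != grid.shape:
        raise ValueError("fluence field and grid shapes differ")
    n_labels = max(grid.properties) + 1
    mu_a = np.zeros(n_labels)
    for lab, props in grid.properties.items():
        mu_a[lab] = props.mu_a
    return (mu_a[grid.labels] * field.fluence).astype(np.float32)


def absorbed_fraction_from_field(field: FluenceField, grid: VoxelGrid) -> float:
    """Σ S·V_voxel / A_beam — the track-length estimate of the absorbed fraction.

    Agrees with the transport ledger's absorbed fraction to floating-point
    accuracy because absorption is deposited continuously along each path
    segment with the exact same integral.
    """
    if field.shape != grid.shape:
        raise ValueError("fluence field and grid shapes differ")
    n_labels = max(grid.properties) + 1
    mu_a = np.zeros(n_labels)
    for lab, props in grid.properties.items():
        mu_a[lab] = props.mu_a
    sums = np.bincount(
        grid.labels.ravel(), weights=field.fluence.ravel(), minlength=n_labels
    )
    total = float(np.dot(mu_a, sums))
    return total * grid.pitch_mm**3 / field.beam.area_mm2


def s_profile(
    field: FluenceField, grid: VoxelGrid, window: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """On-axis S(z): μa·F averaged over the central window of columns."""
    if field.shape != grid.shape:
        raise ValueError("fluence field and grid shapes differ")
    nx, ny, _ = grid.shape
    half = window // 2
    cx, cy = nx // 2, ny // 2
    n_labels = max(grid.properties) + 1
    mu_a = np.zeros(n_labels)
    for lab, props in grid.properties.items():
        mu_a[lab] = props.mu_a
    cols_f = field.fluence[cx - half : cx + half + 1, cy - half : cy + half + 1, :]
    cols_l = grid.labels[cx - half : cx + half + 1, cy - half : cy + half + 1, :]
    s = (mu_a[cols_l] * cols_f).mean(axis=(0, 1))
    z = (np.arange(grid.shape[2]) + 0.5) * grid.pitch_mm
    return z, s


def layer_properties_at(
    table: TissueOpticsTable,
    wavelength_nm: float,
    sd_offset: float = 0.0,
    g: float = DEFAULT_G,
) -> tuple[dict[str, OpticalProperties], bool]:
    """Per-layer OpticalProperties at mean + sd_offset·SD; flags μa clamping."""
    props = {}
    clamped_any = False
    for tissue in table.TISSUES:
        mu_a, mu_sp, clamped = table.coefficients(tissue, wavelength_nm, sd_offset)
        clamped_any |= clamped
        props[tissue] = OpticalProperties.from_reduced(
            mu_a, mu_sp, g, _LAYER_N[tissue]
        )
    return props, clamped_any


def delta_bounds(
    table: TissueOpticsTable,
    blood: BloodTable,
    vessels: VesselParams,
    wavelength_nm: float,
    beam: BeamSpec,
    n_photons: int = 1_000_000,
    seed: int = 0,
    shape: tuple[int, int, int] = (500, 500, 400),
    pitch_mm: float = 0.01,
    window: int = 3,
    g: float = DEFAULT_G,
    n_dermis: float = 1.39,
) -> tuple[float, float, bool]:
    """(δ_min, δ_max) from the (mean + 1 SD) and (mean − 1 SD) property sets.

    Larger coefficients attenuate more, so the +1 SD set yields the minimum
    penetration depth and the −1 SD set the maximum.  Returns
    (delta_min, delta_max, clamped): ``clamped`` reports whether any layer's
    mean − SD absorption had to be floored.

    Blood keeps its tabulated coefficients in both runs (no SD is tabulated
    for whole blood).
    """
    mu_a_b, mu_sp_b = blood.lookup(wavelength_nm)
    blood_props = OpticalProperties.from_reduced(mu_a_b, mu_sp_b, g, n_dermis)

    deltas = {}
    clamped_any = False
    for tag, sd_offset in (("hi", +1.0), ("lo", -1.0)):
        layer_props, clamped = layer_properties_at(table, wavelength_nm, sd_offset, g)
        clamped_any |= clamped
        grid = build_skin_model(
            vessels, blood_props, layer_props, shape=shape, pitch_mm=pitch_mm, seed=seed
        )
        field = simulate_voxel(grid, beam, n_photons, seed)
        deltas[tag] = penetration_depth(field, window=window)

    delta_min, delta_max = deltas["hi"], deltas["lo"]
    if delta_min > delta_max:
        raise AssertionError(
            "attenuation monotonicity violated: +1 SD delta exceeds -1 SD delta"
        )
    return delta_min, delta_max, clamped_any
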