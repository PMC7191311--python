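"""Skin-like synthetic optical-property spectra and noisy Rd/Tt measurements.

The generator produces per-wavelength (μa, μs′) spectra from a small
chromophore model — melanin (power-law rise toward short wavelengths),
hemoglobin (whole-blood anchors interpolated in λ), a water band near
968 nm, a broad bilirubin band between 400 and 500 nm, and a flat baseline —
with reduced scattering following a Rayleigh + Mie power-law decay:

    μs′(λ) = a · [ f_Ray (λ/500)⁻⁴ + (1 − f_Ray) (λ/500)^(−b_Mie) ]

Forward-simulated Rd/Tt "measurements" add multiplicative Gaussian noise at
the calibration bounds of a double-integrating-sphere instrument (Rd: 0.7%
below 1000 nm, 2.5% at and above; Tt: 0.2%), averaged over a configurable
replicate count emulating multi-spot averaging.

The packaged presets (``epidermis-like``, ``dermis-like``, ``fat-like``) are
least-squares tuned so the generated spectra pass within the measured
mean ± 2 SD envelopes of the corresponding skin layers at the nine tabulated
wavelengths.  They exist to exercise the inversion and dosimetry pipeline,
not to serve as literature-grade chromophore spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mc_slab import SlabStack, simulate_slab
from .imc_fit import derive_seed
from .optics_core import (
    DEFAULT_G,
    BloodTable,
    MeasuredSpectrum,
    OpticalProperties,
    load_paper_tables,
)

__all__ = [
    "ChromophoreModel",
    "NoiseModel",
    "make_tissue_spectrum",
    "synth_measurement",
    "PRESETS",
]

#: reference melanin absorption scale: μa of a fully melanized voxel at 694 nm
_MELANIN_REF_MM1 = 13.0
#: peak water absorption (mm⁻¹) of the 968-nm band at unit water fraction
_WATER_PEAK_MM1 = 0.048
_WATER_CENTER_NM = 968.0
_WATER_WIDTH_NM = 45.0
_BILIRUBIN_CENTER_NM = 460.0
_BILIRUBIN_WIDTH_NM = 40.0


@dataclass(frozen=True)
class ChromophoreModel:
    """Parametric tissue model generating μa(λ) and μs′(λ) over 400–1100 nm."""

    melanin_fraction: float = 0.0
    melanin_exponent: float = 3.0
    blood_fraction: float = 0.0
    oxygen_saturation: float = 0.96
    water_fraction: float = 0.0
    bilirubin_amplitude: float = 0.0
    baseline_mu_a: float = 0.02
    scatter_amplitude: float = 4.0  # μs′ at 500 nm (mm⁻¹)
    rayleigh_fraction: float = 0.2
    mie_exponent: float = 1.0

    def __post_init__(self) -> None:
        for name in ("melanin_fraction", "blood_fraction", "water_fraction",
                     "oxygen_saturation", "rayleigh_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} must lie in [0, 1]")
        if self.scatter_amplitude <= 0:
            raise ValueError("scatter amplitude must be positive")
        if self.baseline_mu_a < 0 or self.bilirubin_amplitude < 0:
            raise ValueError("absorption amplitudes must be non-negative")


#: presets tuned against the measured layer coefficients (see module docstring)
PRESETS: dict[str, ChromophoreModel] = {
    "epidermis-like": ChromophoreModel(
        melanin_fraction=0.048,
        melanin_exponent=3.33,
        baseline_mu_a=0.0,
        scatter_amplitude=7.53,
        rayleigh_fraction=0.017,
        mie_exponent=1.285,
    ),
    "dermis-like": ChromophoreModel(
        melanin_fraction=0.0007,
        melanin_exponent=4.5,
        blood_fraction=0.0015,
        water_fraction=0.47,
        baseline_mu_a=0.046,
        scatter_amplitude=4.46,
        rayleigh_fraction=0.069,
        mie_exponent=1.555,
    ),
    "fat-like": ChromophoreModel(
        melanin_fraction=0.0024,
        melanin_exponent=4.5,
        blood_fraction=0.0013,
        water_fraction=0.203,
        bilirubin_amplitude=0.0,
        baseline_mu_a=0.0237,
        scatter_amplitude=2.065,
        rayleigh_fraction=0.042,
        mie_exponent=0.775,
    ),
}


def make_tissue_spectrum(
    model: ChromophoreModel,
    wavelengths_nm: np.ndarray,
    blood: BloodTable | None = None,
    g: float = DEFAULT_G,
    n: float = 1.39,
) -> list[OpticalProperties]:
    """Evaluate the chromophore model at each wavelength.

    Returns one :class:`OpticalProperties` per wavelength, with μs recovered
    from μs′ through the similarity relation at anisotropy ``g``.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    if np.any((wl < 400) | (wl > 1100)):
        raise ValueError("wavelengths must lie within 400–1100 nm")
    if blood is None:
        _, blood, _ = load_paper_tables()

    mel = model.melanin_fraction * _MELANIN_REF_MM1 * (wl / 694.0) ** (
        -model.melanin_exponent
    )
    mu_a_blood, _ = blood.interpolate(wl)
    water = (
        model.water_fraction
        * _WATER_PEAK_MM1
        * np.exp(-(((wl - _WATER_CENTER_NM) / _WATER_WIDTH_NM) ** 2))
    )
    bili = model.bilirubin_amplitude * np.exp(
        -(((wl - _BILIRUBIN_CENTER_NM) / _BILIRUBIN_WIDTH_NM) ** 2)
    )
    mu_a = model.baseline_mu_a + mel + model.blood_fraction * mu_a_blood + water + bili

    ratio = wl / 500.0
    mu_sp = model.scatter_amplitude * (
        model.rayleigh_fraction * ratio**-4
        + (1.0 - model.rayleigh_fraction) * ratio ** (-model.mie_exponent)
    )

    if np.any(mu_a <= 0):
        raise ValueError("model produced non-positive mu_a (check baseline)")
    if np.any(mu_sp <= 0):
        raise ValueError("model produced non-positive mu_s_prime (check amplitude)")
    return [
        OpticalProperties.from_reduced(float(a), float(s), g, n)
        for a, s in zip(mu_a, mu_sp)
    ]


@dataclass(frozen=True)
class NoiseModel:
    """Relative 1-SD measurement noise of the integrating-sphere instrument.

    The defaults are the calibration bounds of the emulated instrument:
    Rd within 0.7% below 1000 nm and 2.5% at/above (reduced sphere
    reflectance and detector sensitivity in the near infrared), Tt within
    0.2%; five-spot averaging per sample.
    """

    rd_rel_below_1000nm: float = 0.007
    rd_rel_above_1000nm: float = 0.025
    tt_rel: float = 0.002
    replicates: int = 5

    def __post_init__(self) -> None:
        if min(self.rd_rel_below_1000nm, self.rd_rel_above_1000nm, self.tt_rel) < 0:
            raise ValueError("noise levels must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")

    def rd_sigma(self, wavelength_nm: float) -> float:
        return (
            self.rd_rel_below_1000nm
            if wavelength_nm < 1000
            else self.rd_rel_above_1000nm
        )


def synth_measurement(
    properties: list[OpticalProperties],
    wavelengths_nm: np.ndarray,
    stack_template: SlabStack,
    thickness_mm: float,
    noise: NoiseModel | None,
    n_photons: int,
    seed: int,
) -> tuple[MeasuredSpectrum, dict]:
    """Forward-simulate a noisy Rd/Tt spectrum from known optical properties.

    Runs the slab Monte Carlo model per wavelength on ``stack_template`` with
    its turbid layer replaced by the given properties and thickness, then
    averages ``noise.replicates`` noisy replicates (independent multiplicative
    Gaussian perturbations at the noise-model levels).  ``noise=None`` (or
    all-zero levels with one replicate) returns the forward model output
    exactly.

    Returns the spectrum and a truth record
    ``{"mu_a": ..., "mu_s_prime": ..., "seed": ..., "n_photons": ...}``
    for recovery scoring.
    """
    from .imc_fit import _sample_layer_index  # shared sample-layer convention
    from .mc_slab import Layer
    wl = np.asarray(wavelengths_nm, dtype=float)
    if len(properties) != wl.size:
        raise ValueError("one OpticalProperties per wavelength required")

    sample_idx = _sample_layer_index(stack_template)
    rng = np.random.default_rng(seed)

    rd = np.empty(wl.size)
    tt = np.empty(wl.size)
    sd_rd = np.zeros(wl.size)
    sd_tt = np.zeros(wl.size)
    for i, props in enumerate(properties):
        layers = list(stack_template.layers)
        sample = layers[sample_idx]
        layers[sample_idx] = Layer(sample.name, props, thickness_mm)
        stack = replace(stack_template, layers=tuple(layers))
        res = simulate_slab(stack, n_photons, derive_seed(seed, i, "synth"), nz_bins=1)
        if noise is None:
            rd[i], tt[i] = res.rd, res.tt
            continue
        s_rd = noise.rd_sigma(wl[i])
        reps_rd = res.rd * (1.0 + s_rd * rng.standard_normal(noise.replicates))
        reps_tt = res.tt * (1.0 + noise.tt_rel * rng.standard_normal(noise.replicates))
        rd[i] = reps_rd.mean()
        tt[i] = reps_tt.mean()
        if noise.replicates > 1:
            sd_rd[i] = reps_rd.std(ddof=1)
            sd_tt[i] = reps_tt.std(ddof=1)

    rd = np.clip(rd, 0.0, 1.0)
    tt = np.clip(tt, 0.0, 1.0)
    # enforce physicality of the averaged replicates
    over = rd + tt > 1.0
    if np.any(over):
        scale = 1.0 / (rd[over] + tt[over])
        rd[over] *= scale
        tt[over] *= scale

    spectrum = MeasuredSpectrum(
        wavelength_nm=wl, rd=rd, tt=tt, thickness_mm=thickness_mm,
        sd_rd=sd_rd, sd_tt=sd_tt,
    )
    truth = {
        "mu_a": np.array([p.mu_a for p in properties]),
        "mu_s_prime": np.array([p.mu_s_prime for p in properties]),
        "g": properties[0].g,
        "n": properties[0].n,
        "seed": seed,
        "n_photons": n_photons,
    }
    return spectrum, truth
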