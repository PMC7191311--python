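"""Forward Monte Carlo transport in a plane-parallel layered sample.

Models the glass-mounted tissue slab of an integrating-sphere measurement:
an ordered stack of layers in air, a normally incident collimated beam, and
weighted-packet transport with Henyey–Greenstein scattering, Fresnel
boundaries and Russian roulette.  The specular reflection of the collimated
beam at the entrance is computed analytically (including the two-interface
correction when the stack is topped by a clear glass slide) and reported
separately from the diffuse reflectance, matching integrating-sphere practice
where the specular beam is dumped into a trap.

Reported quantities per run: diffuse reflectance ``Rd``, specular reflectance
``Rs``, total transmittance ``Tt`` and absorbed fraction ``A``, with
``Rs + Rd + Tt + A = 1`` to floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import slab_kernel
from .optics_core import N_GLASS, OpticalProperties

__all__ = ["Layer", "SlabStack", "SlabResult", "simulate_slab", "glass_mounted_stack"]


@dataclass(frozen=True)
class Layer:
    """One homogeneous layer of a slab stack."""

    name: str
    properties: OpticalProperties
    thickness_mm: float

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError(f"layer {self.name!r} must have positive thickness")


@dataclass(frozen=True)
class SlabStack:
    """Ordered layer stack bounded by semi-infinite ambient media (air).

    The top surface sits at z = 0; layers extend downward.  The incident beam
    is collimated and normal; because the geometry is laterally infinite, a
    pencil beam and a finite flat-top beam produce identical hemispherical
    Rd/Tt, so no beam radius is needed here.
    """

    layers: tuple[Layer, ...]
    n_above: float = 1.0
    n_below: float = 1.0

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def boundaries_mm(self) -> np.ndarray:
        """Cumulative layer boundaries, z = 0 at the top surface."""
        t = np.array([lay.thickness_mm for lay in self.layers])
        return np.concatenate(([0.0], np.cumsum(t)))

    @property
    def total_thickness_mm(self) -> float:
        return float(sum(lay.thickness_mm for lay in self.layers))


@dataclass(frozen=True)
class SlabResult:
    """Tallies of one slab run, as fractions of the incident power."""

    rd: float
    rs: float
    tt: float
    a: float
    se_rd: float
    se_tt: float
    n_photons: int
    seed: int
    #: depth-binned absorbed weight (fraction per bin) and the bin width (mm)
    absorbed_z: np.ndarray = field(repr=False, default=None)
    dz_mm: float = 0.0

    def __post_init__(self) -> None:
        balance = self.rd + self.rs + self.tt + self.a
        if abs(balance - 1.0) > 1e-9:
            raise AssertionError(f"energy ledger violated: sum = {balance!r}")


def glass_mounted_stack(
    tissue: OpticalProperties,
    thickness_mm: float,
    glass_thickness_mm: float = 1.0,
    n_glass: float = N_GLASS,
    include_glass: bool = True,
    name: str = "tissue",
) -> SlabStack:
    """Stack for a tissue slab sandwiched between glass slides in air."""
    tissue_layer = Layer(name, tissue, thickness_mm)
    if not include_glass:
        return SlabStack(layers=(tissue_layer,))
    glass = OpticalProperties(mu_a=0.0, mu_s=0.0, g=0.0, n=n_glass)
    return SlabStack(
        layers=(
            Layer("glass_top", glass, glass_thickness_mm),
            tissue_layer,
            Layer("glass_bottom", glass, glass_thickness_mm),
        )
    )


def _specular_and_start(stack: SlabStack) -> tuple[float, int]:
    """Analytic specular reflectance of the collimated beam at normal incidence.

    For a clear first layer the standard two-interface expression
    ``r1 + (1 - r1)^2 r2 / (1 - r1 r2)`` is used and the packet starts at the
    top of the second layer; otherwise the single-interface Fresnel term
    applies and the packet starts at the surface.
    """
    n0 = stack.n_above
    n1 = stack.layers[0].properties.n
    r1 = ((n0 - n1) / (n0 + n1)) ** 2
    first = stack.layers[0].properties
    if first.mu_a == 0.0 and first.mu_s == 0.0 and len(stack.layers) > 1:
        n2 = stack.layers[1].properties.n
        r2 = ((n1 - n2) / (n1 + n2)) ** 2
        rs = r1 + (1.0 - r1) ** 2 * r2 / (1.0 - r1 * r2)
        return rs, 1
    return r1, 0


def simulate_slab(
    stack: SlabStack,
    n_photons: int,
    seed: int,
    nz_bins: int = 100,
) -> SlabResult:
    """Run the layered Monte Carlo model and tally Rd, Rs, Tt and A.

    Parameters
    ----------
    stack : SlabStack
        Sample geometry; layer properties must be finite.
    n_photons : int
        Photon packets to launch (≥ 1).
    seed : int
        Seed of the transport RNG; fixed seed ⇒ bit-identical result.
    nz_bins : int
        Depth bins for the absorbed-energy profile over the full stack depth.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    mu_a = np.array([lay.properties.mu_a for lay in stack.layers])
    mu_s = np.array([lay.properties.mu_s for lay in stack.layers])
    g = np.array([lay.properties.g for lay in stack.layers])
    n = np.array([lay.properties.n for lay in stack.layers])
    if not np.isfinite(np.concatenate([mu_a, mu_s, g, n])).all():
        raise ValueError("non-finite optical properties in stack")
    zb = stack.boundaries_mm

    rs, start_layer = _specular_and_start(stack)
    w0 = 1.0 - rs
    dz = stack.total_thickness_mm / nz_bins

    rd_sum, tt_sum, a_sum, rd_sq, tt_sq, a_z = slab_kernel(
        mu_a, mu_s, g, n, zb,
        stack.n_above, stack.n_below,
        start_layer, w0,
        n_photons, seed, nz_bins, dz,
    )

    rd = rd_sum / n_photons
    tt = tt_sum / n_photons
    a = a_sum / n_photons

    def _se(total: float, sq: float) -> float:
        mean = total / n_photons
        var = max(0.0, sq / n_photons - mean * mean)
        return float(np.sqrt(var / n_photons))

    return SlabResult(
        rd=rd,
        rs=rs,
        tt=tt,
        a=a,
        se_rd=_se(rd_sum, rd_sq),
        se_tt=_se(tt_sum, tt_sq),
        n_photons=n_photons,
        seed=seed,
        absorbed_z=a_z / n_photons,
        dz_mm=dz,
    )
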