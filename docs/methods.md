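# Methods

`skinoptics` models light transport in layered human skin in three stages:
a forward Monte Carlo model of glass-mounted tissue slabs (the geometry of a
double-integrating-sphere measurement), an inverse Monte Carlo (iMC) search
that recovers the absorption coefficient μa and reduced scattering
coefficient μs′ of a slab from its diffuse reflectance Rd and total
transmittance Tt, and a voxelized three-layer skin model with dermal
vasculature used to compute the optical penetration depth δ and the energy
deposition S at clinical laser wavelengths.

## Radiative-transport model

Photon packets carry a statistical weight in [0, 1] and propagate with free
paths drawn from the local interaction coefficient; scattering deflections
follow the Henyey–Greenstein phase function with anisotropy g (default 0.9,
a typical soft-tissue value), refraction and reflection at index boundaries
use the unpolarized Fresnel coefficients with total internal reflection, and
low-weight packets are terminated by Russian roulette (threshold 1e-4,
survival odds 1/10, the conventional choices). Units are mm and mm⁻¹
throughout; μs is recovered from μs′ through the similarity relation
μs = μs′/(1−g).

Two engines share this physics:

* **Slab engine** (`mc_slab`) — plane-parallel layers, laterally infinite.
  The specular reflection of the collimated normal beam is computed
  analytically (two-interface formula when the stack is topped by a clear
  glass slide) and reported separately from Rd, matching integrating-sphere
  practice where the specular beam exits through the entrance port or is
  trapped. Absorption uses the collision estimator (weight drop
  W·μa/(μa+μs)), tallied into depth bins. The measured sample is modeled as
  tissue between two 1.0-mm glass slides (n = 1.52), configurable off.
* **Voxel engine** (`skin_voxel`) — mcxyz-style transport on a uniform
  voxel grid with per-voxel tissue labels. Voxel indices are advanced
  face-by-face (distances are measured from positions, but the indices are
  authoritative, which makes the traversal immune to floating-point
  face-sticking). Absorption is applied continuously along each
  voxel-confined segment (the weight decays as exp(−μa·ℓ)) and the
  track-length fluence tally accumulates the exact path integral of the
  decaying weight, so the identity Σ μa·F·V/A_beam = absorbed fraction holds
  algebraically, not just in expectation. The refractive mismatch is applied
  only at the air/skin surface (internal indices unified at the epidermis
  value 1.34, the mcxyz convention); packets crossing the lateral or bottom
  faces escape and are tallied per face so domain truncation is always
  visible in the output.

**Energy bookkeeping is exact per run.** Russian roulette is made
ledger-neutral: a killed packet's weight is charged to the absorbed tally
and the survival bonus (9×W) is credited against it. Both charges cancel in
expectation, leaving every tally unbiased, while Rs + Rd + Tt + A = 1 (slab)
and absorbed + escaped = 1 (voxel) hold to ~1e-12 in every run. The tests
assert 1e-9.

**Randomness.** Both engines draw from an inline xorshift64* generator
seeded through a splitmix64 scramble of a user seed; a fixed seed gives
bit-identical results. All pipeline stages derive their seeds from a single
user seed via SHA-256 (`derive_seed`), and every result object records the
seed it was produced with.

A deliberately simple pure-Python scalar reference implementation
(`reference.py`, standard-library Mersenne Twister, fresh free-path draw
after each boundary crossing) shares no code with the engines and serves as
an independent cross-check in the test suite.

## Inverse Monte Carlo fit

Per wavelength the fit searches the (μa, μs′) plane for the pair whose
forward-simulated (Rd, Tt) matches the measurement. The objective is the
larger of the two relative differences; a pair is *accepted* only when both
relative differences are ≤ the tolerance (0.5% by default) in a verification
run at the full per-evaluation photon budget (2×10⁵ by default) with a seed
independent of the search. Both residuals must pass individually — the
plural reading of the acceptance condition — and ties on the grid break
toward the smallest μa, then the smallest μs′.

The search proceeds in stages:

1. **Range estimation.** A coarse sweep of the full bounds
   (μa ∈ [0.001, 10], μs′ ∈ [0.1, 20] mm⁻¹, generous envelopes of all
   packaged skin values) at 1.0 mm⁻¹ increments, then the 0.1 mm⁻¹ grid
   within the winning ±1.0 window, both at reduced photon budgets. This
   replaces an exhaustive 0.1-increment sweep of the full bounds (~2×10⁴
   forward runs), which adds nothing once the basin is located.
2. **Valley-aware refinement.** Rd/Tt of skin-like slabs are 20–30× more
   sensitive to μa than to μs′ (measured at the dermis operating point:
   ∂lnTt/∂μa ≈ −6.5 per mm⁻¹ vs ∂lnTt/∂μs′ ≈ −0.24 per mm⁻¹), so the joint
   objective has a long diagonal valley with floor slope dμs′/dμa ≈ −25.
   Halving a single shared increment resolves μa but strands the search far
   up the valley: each μa step demands a ~25× larger μs′ correction than
   any ±2-increment window can carry. Refinement therefore halves the μa
   increment each round while stepping μs′ on a grid 4× coarser (never
   coarser than the initial 0.1 mm⁻¹), and each round's ±2-increment window
   *walks*: if the minimizer lands on the window edge, the window is
   re-centred there and re-swept (cached evaluations keep overlaps cheap).
   The ratio 4 keeps the μs′ lattice at acceptance fine (≲0.5% of a
   skin-like μs′) so grid quantization does not dominate the recovered
   values. Refinement stops at acceptance, at increment < 1e-4 mm⁻¹, or
   after `max_rounds` (12); a wavelength that never clears the tolerance is
   returned with `converged = False`, never silently accepted.
3. **One fixed search surface per phase.** Candidates are evaluated with
   one shared derived seed (common random numbers), making the search
   deterministic given (seed, spectrum); under a shared seed the objective
   varies smoothly with the parameters, so the walking descent reliably
   finds the surface's basin minimum. The surface's absolute Monte Carlo
   offset ε displaces the valley minimum by roughly ε/0.14 in μs′, so the
   fine rounds (increment ≤ 0.02 mm⁻¹), which fix the accepted pair, use
   the full search budget (1.2×10⁵ photons by default, offset ≈ 0.03 mm⁻¹
   in μs′ — inside what verification accepts), while the coarse travel
   rounds use a quarter of it. A failed verification doubles the search
   budget (capped at the verification budget). Verification attempts are
   triggered once the search objective is within 1.5× the tolerance,
   because the search surface carries its own noise floor; acceptance
   itself always requires verified residuals ≤ the tolerance.

The measured Rd/Tt sensitivities at the dermis-like operating point
(∂lnTt/∂μa ≈ −6.5 per mm⁻¹, ∂lnTt/∂μs′ ≈ −0.24 per mm⁻¹) mean the 0.5%
acceptance band pins μa to ~±0.001 mm⁻¹ and μs′ to ~±0.02 mm⁻¹; the
refinement reaches those increments in 7–8 rounds.

## Voxel skin model

The default grid is 500 × 500 × 400 voxels of 10 μm (5 × 5 × 4 mm), skin
surface at z = 0, beam centered laterally: epidermis to 0.15 mm, dermis to
1.65 mm, subcutaneous fat below. Blood vessels are embedded as
blood-labelled voxels from the packaged vasculature table:

* capillary plexus — 10-μm (one-voxel) cylinders of 0.5 mm length placed at
  seeded random positions in the 150-μm band centered at 230 μm until the
  in-band blood volume fraction reaches 4%;
* upper (Ø 50 μm at 340 μm) and deep (Ø 80 μm at 1210 μm) plexuses —
  periodic cylinders along x. Odd voxel diameters center the rasterized
  circle on a voxel center, even diameters on a voxel boundary, so the
  footprint spans exactly the nominal diameter; the center-to-center spacing
  is the nearest integer voxel count that makes the *rasterized* in-band
  fraction exact (area 21 voxels / band 5 × 14 → 30.0%; 52 / (8 × 65) →
  10.0%), in preference to rounding the continuous-geometry spacing
  π·d/(4f), which would miss the target fraction by ~2 points.

The in-band fraction reading of the vessel table (band height = one vessel
diameter; 150 μm for the capillary band) is adopted because a 30% blood
fraction over the whole dermis would be non-physiological. Vessel
orientation is not specified by the source data; parallel x-cylinders
(with one cylinder anchored on the beam axis) and randomized capillary
segments are the simplest structures meeting the depth/fraction/diameter
constraints, and the capillary seed is recorded in the grid. Blood reuses
the dermis refractive index; since internal mismatches are ignored anyway,
only the surface index matters to the transport.

At 10-μm pitch the band quantization places the capillary band at
160–310 μm and shifts plexus centers by at most half a voxel (5 μm).

## Dosimetry

Fluence is normalized to the delivered beam irradiance (incident photons per
beam area), so the field is dimensionless and ≈ (1 − specular) just below
the surface of a transparent medium; near-surface values above 1 are real
(backscatter build-up). δ is the depth at which the on-axis profile —
averaged over the central 3 × 3 voxel columns (configurable to 1 × 1) to
trade a 30-μm blur for Monte Carlo variance — first falls below 1/e of the
incident irradiance *and stays below for the next voxel* (a single-voxel dip
does not count), interpolated linearly in log-fluence between the
bracketing voxel centers. Defining the normalization by the delivered
irradiance (not the backscatter-augmented subsurface fluence) keeps δ
well-defined when the near-surface fluence exceeds 1.

Uncertainty bounds on δ follow from the measured layer dispersions: the
maximum δ uses the (mean − 1 SD) coefficient set for all three layers, the
minimum δ the (mean + 1 SD) set. Where mean − SD would be non-positive
(possible for the weakly absorbing entries), μa is floored at 1e-4 mm⁻¹ and
the result is flagged. Blood keeps its tabulated values in both runs (no SD
is tabulated for whole blood).

S = μa·F per voxel (mm⁻¹ per unit incident irradiance) is the heat source
for photothermal modelling; its volume integral divided by the beam area
reproduces the absorbed fraction exactly (see the track-length identity
above).

Two cautions on closed-form cross-checks. The deep-fluence decay rate
μeff = √(3μa(μa+μs′)) is a *laterally infinite, plane-illumination*
asymptote: the slab engine reproduces it to ~2% on the 1–3 mm window, but
the on-axis profile of a 3–4 mm beam on the 5 × 5 mm default grid decays up
to twice as fast (finite-beam spreading plus ~40% lateral escape), so
diffusion-theory comparisons in the tests use the slab geometry, and δ is
compared against 1/μa in a ballistic (pure-absorber) configuration where
the closed form is exact. The escape tallies make the truncation of the
default grid visible per run.

## Synthetic data

The generator exists to exercise the estimation pipeline with known truth,
not to provide literature-grade chromophore spectra. μa(λ) is a baseline
plus melanin (power law normalized at 694 nm, exponent ~3–4.5), whole-blood
absorption interpolated linearly between the nine packaged anchors at 96%
oxygen saturation, a Gaussian water band at 968 nm (σ = 45 nm) and a
Gaussian bilirubin band at 460 nm; μs′(λ) is the standard Rayleigh + Mie
mixture a·[f_Ray(λ/500)⁻⁴ + (1−f_Ray)(λ/500)^(−b_Mie)]. The three presets
were least-squares tuned against the packaged layer table and pass within
the measured mean ± 2 SD envelopes at all nine wavelengths (the dermis-like
preset is within 1 SD at 632 nm).

Measurement noise emulates the instrument calibration bounds, interpreted
as 1-SD relative Gaussian levels: Rd 0.7% below 1000 nm and 2.5% at/above
(reduced sphere reflectance and detector sensitivity in the near infrared),
Tt 0.2%, with five-replicate averaging emulating multi-spot measurements.
What the generator does not emulate: inter-sample biological variability
(the dominant dispersion in the packaged tables), wavelength-correlated
instrument drifts, sample-thickness uncertainty, and residual blood in
nominally bloodless slabs. Passing recovery tests therefore demonstrate
correctness of the estimator under the stated noise model, not field
performance on real tissue.

## Problem sizes and numerical choices

Desk-scale defaults keep a full run on one CPU core practical: 2×10⁵
photons per forward slab evaluation (the acceptance verification budget),
10⁶ photons per voxel run (the full-scale setting of 1.8×10⁸ is a
parameter), and the default 500×500×400 grid. The test suite uses reduced
photon counts and coarser grids where only correctness, not precision, is
at stake; the parameter-recovery sweep runs at a relaxed 1.5% tolerance
consistent with its reduced budgets. Degenerate inputs are handled
explicitly: zero interaction coefficients propagate ballistically, a zero
measured quantity switches the relative difference to an absolute
comparison against a 0.03 floor (flagged), horizontal packets in clear
layers and pathological boundary-bounce loops are terminated into the
absorbed tally (bounded at 10⁶ boundary events).

## Known limitations

* Rd/Tt are total hemispherical quantities; sphere port geometry and
  lateral losses of a real double-sphere instrument are not modeled.
* No polarization, no time resolution, wavelength-independent refractive
  indices (fixed at 1.34/1.39/1.44 per layer, their ~633 nm values).
* The inverse fit estimates (μa, μs′) with g and n fixed; g itself is not
  identifiable from Rd/Tt alone (which is also why the recovered pairs are
  insensitive to the assumed g).
* Vessel topology beyond the depth/fraction/diameter triple is an
  interpretation; real dermal plexuses are networks, not parallel tubes.
* The 4-mm grid depth truncates subcutaneous fat at the most penetrating
  wavelengths; the bottom-escape tally quantifies the loss per run.
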