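# Methods

`pasim` simulates the design chain of a dual-arm, linear-array handheld
photoacoustic (PA) probe: how much pulsed light reaches a depth in a
scattering medium, how an absorbing micro-target converts it into an
acoustic transient, and what the ultrasound array can resolve. This note
records the models, their assumptions, the parameter conventions, and the
places where the design was genuinely open.

## Light transport (`optical_transport`)

Light propagation in a highly scattering medium (μa ≪ μs′) is described by
the diffusion approximation

    (n/c) ∂φ/∂t − ∇·(D ∇φ) + μa φ = P0,    D = 1/(3 (μs′ + μa)),

with φ the fluence, μs′ = (1−g) μs the reduced scattering coefficient, and
a Robin condition −D ∇φ·n̂ = h φ on every outer face. The boundary
coefficient h = ½ (1−R_eff)/(1+R_eff) uses the Egan–Hilgeman curve fit for
the effective internal reflection R_eff(n). The reference medium is 1%
Lipofundin (μa = 0.026 cm⁻¹, μs′ = 6.31 cm⁻¹, n = 1.35 at 785 nm), a
standard tissue-mimicking emulsion.

**Discretization.** Cell-centered finite differences with a 7-point
Laplacian on a regular grid; the Robin condition enters by ghost-cell
elimination, which makes the scheme conservative — the discrete energy
audit (absorbed + boundary loss = injected) closes to solver tolerance,
and the test suite asserts it. The steady (time-integrated) equation is a
single symmetric positive-definite sparse solve (Jacobi-preconditioned
CG, relative tolerance 1e−9); the transient equation is integrated by
Crank–Nicolson with Δt = τp/20 (the n/c storage term makes the equation
extremely stiff, so an implicit scheme is the only practical option).

The default domain is 160 × 80 × 50 mm at 1.0 mm spacing (640k cells,
~3 s per steady solve). With the anti-aliased source rasterization below,
the midline design observables change by <0.5% when the spacing is halved
to 0.5 mm, so the finer grid is not the default. The steady mode is used
for all design sweeps: the reported quantities are relative fluences at
fixed positions, which are identical for the time-integrated field.

**Source model.** Each fiber arm outputs a 16.5 × 0.8 mm rectangular beam
(NA 0.22). Ballistic photons randomize after one transport mean free path
Z0 = 1/(μa + μs′) ≈ 1.58 mm; each arm is therefore represented by a
rectangular diffusive source patch of the diverged footprint, computed by
growing each beam dimension by one total increment Z0·tan(asin(NA/n)) —
the convention that reproduces the quoted 16.76 × 1.06 mm footprint.
Patches are one cell thick, rasterized with fractional per-axis coverage
weights (anti-aliasing; integer-cell rasterization dominated the grid
convergence error before this). Total injected energy is
Wp·(1 − surface reflection), with the reflection fixed at 5% for all
angles (skin-like; configurable).

**Tilt convention (open design point).** How the incident angle α places
the diffusive patches is not derivable from first principles at this
level of model. Candidate conventions (inward/outward lateral shift, full
or cos α depth, cos α intensity scaling) were screened against the
published angle-sweep behaviour of this illumination design using a
patch-integrated dipole (extrapolated-boundary) diffusion model. The
adopted convention — patch at vertical depth Z0, lateral shift Z0·sin α
*away* from the midline, total energy conserved — reproduces the reported
angle-deficit curve (≈24% at 3 mm, ≈14% at 11 mm for 85° vs 15°) and is
the package default. Scaling the source by cos α instead makes the
deficit ≈90% at every depth and is clearly wrong for this system. With
this convention the simulated 30-vs-10 mm interval fluence ratio at
10 mm depth is ≈26% (reported: 18.8%), and the 14-vs-22 mm contrast is
≈1.7-fold (reported: 3.35); no diffusion-consistent source placement we
probed reproduces both printed interval numbers simultaneously — a
smooth fluence-interval curve through the 18.8% endpoint caps the
14/22 contrast near 2-fold.

**Normalization.** The temporal source prefactor is implemented exactly
as printed, P0 ∝ μs′ Wp (2/(π√π τp)) exp(−4(t−τc)²/τp²), whose time
integral is μs′ Wp/π; a quadrature oracle in the tests pins this down.
Only relative fluences enter any reported observable, so the 1/π does not
propagate anywhere.

## PA generation (`pa_generation`)

The micro-scale chain for a graphite sphere (radius 6 µm) in a 300 µm
sphere of 1% Lipofundin:

1. Heat deposition Q = φ μa Y (heat yield Y = 1 by default).
2. Transient conduction ρC ∂T/∂t = ∇·(k∇T) + Q in spherical symmetry
   (conservative finite volumes, implicit Euler, harmonic-mean interface
   conductivity, outer Dirichlet T = T_ref). The storage term carries ρ;
   dimensional consistency requires it even where source material omits
   it.
3. Thermal strain ε = β·(T̄ − T_ref) of the volume-averaged target
   temperature, taken positive on heating (expansion), giving the radial
   surface displacement u = a·ε and, after Gaussian smoothing over one
   time step, the boundary acceleration ü.
4. Acoustic radiation: (1/(ρc_s²)) ∂²p/∂t² = ∇·(∇p/ρ) outside the target
   with ∂p/∂r = −ρü at the target surface. The substitution ψ = r·p makes
   the spherically symmetric problem exactly one-dimensional
   (ψ_tt = c²ψ_rr) and the outgoing condition ψ_t + c ψ_r = 0 exactly
   non-reflecting, so the radial solver has no artificial boundary error.
   A 2-D X-Z slice solver (leapfrog with first-order Mur edges, the
   target surface driven by the radial solution) renders wavefield
   snapshots; it is a rendering aid, not the quantitative path.

Pressure inside the solid target is not modelled (the surface acts as a
prescribed-acceleration boundary), and the solid eigenresponse is reduced
to the quasi-static strain-displacement map; Young's modulus and Poisson
ratio ride along in the material type but are unused by the default path.

Absolute material constants for graphite and Lipofundin (C, k, ρ, β, c_s)
are shipped as documented defaults in `pa_generation`; published sources
for this class of experiment do not pin them down, so every quantitative
claim built on this module is a ratio in which they cancel. The tests
check the chain's linearity (peak pressure ∝ pulse energy ∝ μaY), 1/r
far-field decay, wavefront kinematics at c_s, causality, and an insulated
enthalpy oracle.

## Array imaging (`us_array_imaging`)

The 128-element, 0.10 mm pitch linear array (18.5 MHz center, 67% −6 dB
fractional bandwidth, 62.5 MHz sampling) is modelled with:

- a Gaussian-enveloped cosine pulse whose −6 dB two-sided spectral width
  equals 0.67·fc (σ_f = BW/(2√(2 ln 2)));
- per-element RF for ideal point scatterers: exact analytic evaluation of
  the delayed pulse (no resampling error), reflectivity weighting,
  hard-baffle directivity sinc(π w sinθ/λ) with element width 0.9·pitch,
  and 1/d spherical spreading. Pulse-echo mode assumes plane-wave
  transmit (d_tx = z); one-way mode is the PA-reception case;
- delay-and-sum beamforming with a dynamic receive aperture limited to
  f-number 1.0 and Hann apodization (both configurable), envelope via the
  analytic signal along the axial axis, log compression for display only;
- FWHM measured on the linear envelope with linear interpolation at the
  half-maximum crossings.

Sound speed defaults to 1540 m/s. Two-point resolvability uses a ≥3 dB
valley between the two highest peaks on either side of the midline, with
a comparable-peak guard (lower ≥ half the higher) so that interference
sidelobes of a merged mainlobe are not counted as a resolved target.

**What this model reproduces and what it cannot.** With the default
settings the center lateral FWHM at 10 mm is ≈189 µm and the map over the
±6 mm × 3–15 mm area spans ≈180–315 µm with strong edge degradation —
both in close agreement with the published resolution study of this
probe. Two published numbers are not reachable from the published array
parameters alone: (a) the axial FWHM (reported ≈167 µm) implies an
effective ~4-cycle pulse, whereas a 67%-bandwidth Gaussian pulse is
~2 cycles and yields envelope-FWHM·c/2 ≈ 56 µm — the reference system's
proprietary transmit waveform and element impulse response evidently
dominate its axial response; (b) a ≥3 dB two-point dip mathematically
requires separations ≳1.3× the lateral FWHM, so a 186 µm-FWHM system
cannot give 3 dB dips at 150–190 µm separations; the package measures
minimum resolvable separations of 240 µm. Narrower settings (rect
apodization) would reproduce the two-point numbers instead of the FWHM
number; the declared defaults are kept for both. Also note that
constant-f-number dynamic-aperture beamforming makes lateral resolution
nearly depth-independent by construction (the aperture grows with depth),
so the qualitative "deeper is worse" lateral trend appears only once the
physical aperture saturates.

## Unmixing (`spectral_unmixing`)

Per-pixel inversion of μa(λ) = ε_HbO2(λ)[HbO₂] + ε_Hb(λ)[Hb] at 750 and
850 nm, then HbT = [HbO₂]+[Hb] and SO₂ = [HbO₂]/HbT. Pixel intensities
are treated as relative μa — the instrument's maps are normalized, and no
fluence-depth compensation is applied by default. Pixels with
non-positive HbT or SO₂ outside [−0.05, 1.05] are masked invalid;
in-range SO₂ is clipped to [0, 1] (thresholds configurable). A bundled
extinction table carries representative NIR Hb/HbO₂ values (isosbestic
near 800 nm); all quantitative tests are synthetic round-trips, so the
table's absolute values are not load-bearing. The 800 nm image serves as
a CBV proxy (proportional to HbT at the isosbestic point), normalized to
a reference-region mean. `wavelength_intensity_balance` reproduces the
procedure of equalizing fluence between two wavelengths at a stated depth
by the ratio of solved fluences; it reports whatever the configured
optical properties imply rather than any fixed percentage.

## Reconstruction (`recon_viz`) and phantoms (`phantoms`)

B-scan stacks (default 0.05 mm Y step) are projected by per-column
maximum intensity (Z projection = TopView, X = SideView); C-scan slices
are planes or thin-slab maxima (a full-range slab reproduces the TopView
MIP exactly, and a brute-force oracle pins the MIP down in tests). Depth
coding restricts the TopView to a depth window (default 8.5–11 mm) and
encodes each pixel's argmax depth as hue and its max as brightness.
Overlays render US in grayscale with PA above a dB threshold (default
−20 dB) in color, leaving sub-threshold pixels bit-identical.

Phantom generators are pure functions of their parameters and seed:

- **two-hair**: two 150 µm cylinders at 10.2 mm depth with a 180 µm gap,
  read as *edge-to-edge* (center-to-center 330 µm; a center-to-center
  reading of 180 µm would physically overlap two 150 µm hairs);
- **multi-target**: one 500 µm lead, two 250 µm threads, one 150 µm
  curved hair, crossing within a 35 mm scan, all inside 8.5–11 mm depth.
  Relative μa values (1.0/0.6/0.4) are chosen only to make depth-coded
  renderings legible;
- **vessel / oxygenation scenes**: synthetic stand-ins for in-vivo data
  (branching surface tubes with an optional 80% occlusion + ground-truth
  mask; a hypoxic disc with SO₂ 0.3–0.6 in 0.9–0.98 background with
  physiological ~150 µM HbT). What passing tests show is that the
  *analysis chain* is exact and noise-stable — not that real tissue obeys
  the two-chromophore model.

Rasterization is distance-to-centerline voxelization (converging to
analytic volumes as spacing shrinks); `phantom_scatterers` exports
centerline intersections with a B-scan plane as point scatterers with
reflectivity ∝ relative μa × diameter.

## Configuration and determinism (`cli_io`, `cli`)

YAML configs with blocks medium/pulse/illumination/grid/array/scene;
every default is the reference system value (20 mJ / 5 ns pulse,
16.5 × 0.8 mm beams, NA 0.22, 5% reflection, 14 mm interval, 35°,
128 elements / 0.10 mm / 18.5 MHz / 67%). Unknown keys are rejected by
name; unit strings are rejected (units are fixed by the schema). Every
pipeline output carries a config hash, and deterministic stages produce
identical HDF5 payloads across runs. A single seed drives the only
stochastic pieces (noise phantoms). The `pasim` CLI is a thin wrapper
over the library.

## Problem sizes

Design solves run on the full domain at 1.0 mm spacing; the analytic
Green's-function verification uses a 60 mm cube at 0.75 mm (max deviation
4.3% over r = 2–15 mm); PSF maps use a 1 mm position step (169 cycles);
two-point sweeps use the 100–400 µm / 10 µm grid. The acceptance script
recomputes everything from scratch in about a minute on one core.

## Known limitations

No Monte Carlo transport, no layered or heterogeneous media, no
wavelength-dependent coefficient library (one scalar pair per run). The
acoustic imaging model has no elevation focusing, speckle, or attenuation
dispersion; the transmit scheme is idealized plane-wave. The PA solver
excludes the target interior. Hemoglobin unmixing is two-chromophore
only. These match the scope of the design study the package reproduces.
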