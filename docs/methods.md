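# Methods

This note records the models implemented in `tfusplan`, the assumptions
behind them, the numerical choices, and the limits of what the synthetic
phantom experiments can show.

## Anatomy and acoustic properties

Volumes are axis-aligned rectilinear grids in millimetres; axes follow the
anatomical convention x = left-right (sagittal normal), y =
anterior-posterior (coronal normal), z = inferior-superior (transverse
normal).  CT volumes are resampled to isotropic spacing (default 1 mm,
trilinear; output dimensions `round(extent/spacing)`) and binarized at
H ≥ 100 HU — the comparison is inclusive and configurable.

Skull acoustic properties derive from porosity ψ = 1 − H/1000, clamped to
[0, 1] because clinical CT exceeds 1000 HU in cortical bone and reaches
−1000 HU in air.  Within the skull mask, sound speed and density
interpolate linearly between water (ψ = 1) and compact bone (ψ = 0);
the attenuation prefactor follows α₀ = α_min + (α_max − α_min)·√ψ.  The
mixing rules apply *only* inside the mask: evaluated at ψ = 1 the
attenuation rule yields 208.9 Np/MHz^y·m, five orders of magnitude above
the water value of 3.48 × 10⁻⁴, so applying it to water voxels would be
unphysical.  Brain and CSF are approximated as water, and the skull is
assumed immersed in water for coupling.  Attenuation prefactors are
power-law coefficients at 1 MHz with a fixed exponent y = 1.51;
α(f) = α₀ (f/1 MHz)^y.

The synthetic phantom is a closed spherical bone shell (configurable
radius, thickness and HU, optionally a radial HU profile) on a
water-equivalent background with an interior target point.  Default study
geometry: outer radius 26 mm, thickness 6 mm, 700 HU.  The radius keeps
the RP candidate shell non-empty under the default contact clearance and
places candidates 27–31 mm from a central target, the stimulus-distance
band a 30 mm radius-of-curvature bowl wants.  What the phantom does *not*
emulate: non-spherical geometry, spatially varying thickness and porosity,
sutures, scalp and soft tissue, and table/frame structures; conclusions
about patient-specific beam paths do not transfer.

## Pulsed drive

A sonication is a rectangular-gated tone train: carrier FF inside bursts
of width TBD repeating at PRF for a total SD.  Defaults: 500 kHz, 200 µs,
300 Hz, 500 ms, 1 MPa — duty cycle TBD·PRF = 6%, SD·PRF = 150 burst
periods, FF·TBD = 100 carrier cycles per burst.  The steady-state
amplitude map needs only one burst at cyclic steady state (a 200 µs burst
is 100 cycles, far past ring-up), so acoustic runs drive a ramped
continuous sinusoid; the full schedule matters only for time-averaged
heating, where it enters through the duty cycle and the on/off windows.

## k-space pseudospectral solver

The solver steps the first-order linear acoustic system (momentum,
continuity, pressure closure) with spectral spatial derivatives on
staggered grids and the k-space temporal correction sinc(c_ref·k·Δt/2),
making propagation exact in homogeneous regions at any CFL ≤ 1; the
reference speed is the medium maximum, and Δt = CFL·Δx/c_max with
CFL = 0.3.  Heterogeneous density uses midpoint-averaged staggered
density.  Power-law absorption enters the pressure closure through the
two fractional-Laplacian terms (absorption ∝ k^{y−2} on ∂ρ/∂t, dispersion
∝ k^{y−1} on ρ) with coefficients τ = −2α₀'c^{y−1},
η = 2α₀'c^y tan(πy/2).  A perfectly matched layer (default 10 voxels,
quartic profile, strength 2) absorbs outgoing waves; setting its width to
0 on an axis leaves that axis periodic.  The stepping core is
dimension-agnostic — 1D/2D/3D share it, with real FFTs throughout.

Numerical properties established by the test suite: machine-precision
energy conservation of the closed lossless scheme (with the time-centred
kinetic pairing of the staggered discretisation); plane-wave phase speed
within 1%; Beer–Lambert decay within 2% at tissue-scale absorption.  The
absorption model is first-order accurate in α₀: at bone-level prefactors
(α₀ ≈ 100 Np/MHz^y·m) the second-order coupling between the absorption
and dispersion terms (absent at y = 2, growing with |tan(πy/2)|) shifts
the effective decay by ~5%.  That is a property of the model, shared by
its standard implementations, not a discretisation artifact — hence the
validation uses moderate α₀.

Sources are spherical-cap (2D: arc) rasterisations of the bowl: voxels
within half a voxel of the sphere of radius ROC about the centre of
curvature, inside the cap half-angle arcsin(d/2ROC).  Drive is injected in
Dirichlet mode (pressure imposed on active voxels), so the surface
pressure equals the configured source pressure; an additive mass-source
mode exists but its amplitude calibration is discretisation-dependent.
The instability guard aborts when |p| exceeds 50× the drive: genuine
blow-ups grow by orders of magnitude within tens of steps, while tight
bowls legitimately exceed 10× focal gain.

The amplitude map is max |p| per voxel over a trailing measurement window
(default 10 carrier periods after 40 settle periods).  A time-gated
window is available and used for focal-geometry fields: max |p| over a
few periods from the direct wavefront's water-path arrival at the target.
This is the hydrophone time-gating practice; it isolates the direct
focused beam from reverberation, which in a closed cavity reaches a
substantial fraction of the focal peak at steady state.

Nonlinearity: the propagation model is linear.  B/A = 5.2 is stored with
the medium for completeness, but solids generate negligible nonlinearity
and the study operates in the linear regime; no nonlinear term is
enabled by default.  Shear waves are not modelled — placements with
incidence beyond 45° carry an explicit caveat flag instead.

## Radius positioning

Candidates are screened in four literal steps: (1) the solid ball of
radius ROC (+ configurable margin) about the target; (2) skull voxels in
the ball set the mean distance to the model centre (per-axis midpoint of
the skull's occupied extent); (3) candidates are ball voxels outside the
flood-filled skull volume with centre distance above that mean — the
flood fill guarantees zero intracranial candidates by construction;
(4) candidates closer to the bone surface than the contact clearance
(default: the bowl's cap depth, 2.73 mm for ROC 30/⌀25) are removed.
All four exclusion counts are reported.  If no skull voxel lies within the
ball, positioning raises an explicit "no reachable placement" error.

Each candidate is evaluated by simulating the bowl aimed at the target
and reading the steady-state amplitude at the target voxel; the argmax
wins, with ties broken by smaller target distance, then lexicographic
voxel order.  The bowl's geometric focus sits one ROC down the aiming
axis — for candidates nearer than ROC the target is deliberately inside
the focal distance, exactly as a fixed-geometry transducer would be used.
Candidate evaluation defaults to 2D: the property maps are sampled
nearest-neighbour on the plane spanned by the beam axis and an in-plane
perpendicular, and the simulation runs on that slice.  This preserves the
thickness and incidence angle of bone along the beam but replaces
spherical by cylindrical spreading; amplitudes are therefore comparable
*between* candidates, not absolutely.  Full-3D evaluation is available
behind a grid-size guard (≤ 128 voxels per axis).  Candidate subsampling
(stride and/or seeded random cap) keeps desk-scale runs tractable; the
seed governs only this subsampling — the physics is deterministic.

## Focal metrics

The focal region is the connected set of voxels ≥ 0.5 of the normalising
peak (half-maximum pressure, −6 dB; an intensity-based −3 dB option
exists).  Length is the region's extent projected on the beam axis, width
its largest perpendicular extent (within the transverse plane when so
requested), and the offset angle is between the region's second-moment
principal axis and the beam axis.  For transcranial fields the analysis
is restricted to a ball (default radius 15 mm) around the expected focus:
with weak post-skull focal gain the raw half-max contour merges with the
incident-beam corridor and with reverberation, and the `degenerate` flag
records whenever this clipping (or the domain boundary) actually cut the
region, so merged cases stay visible.  On the 2D phantom the transcranial
focus comes out slightly *larger* than the water reference (aberration
broadening); patient-scale 3D skulls, with much higher focal gain, show
shrinkage instead — the deviation report carries signs accordingly
(positive = smaller/weaker through bone).

Beam-path angles are arcsin |v·n| against the three anatomical plane
normals; the squared sines sum to one, which the suite asserts to 1e-9
and which the published mean-angle convention satisfies within 0.2%.
Safety indices use the simulated in-situ peak rarefaction pressure
without derating: MI = p⁻[MPa]/√f[MHz] (FDA bound 1.9), I_SPPA = p²/2ρc
with water ρc at the focus (bound 190 W/cm²), I_SPTA = I_SPPA × duty.

## Bioheat

Heat deposition closes the acoustic-thermal loop with the plane-wave
absorption law Q = α(f)·p²/ρc, duty-averaged within each sonication
window; individual 200 µs bursts are not resolved because thermal
diffusion over one burst period is negligible (diffusion length « voxel),
while the 500 ms windows themselves are stepped.  The Pennes equation is
integrated with an explicit conservative finite-difference scheme
(arithmetic-mean face conductivities, zero-flux boundaries) under the
stability bound Δt ≤ Δx²/(2·ndim·max D); the default step is 80% of the
bound.  Perfusion defaults to zero but the sink term is available.
Thermal constants: skull C = 1300 J/kg/K, k = 1.16 W/m/K; water
C = 4178 J/kg/K, k = 0.54 W/m/K.  The printed source for the water
conductivity carries W/cm units that would make water conduct like a
metal; it is interpreted as 0.54 W/m/K (the handbook value), and all four
constants are overridable.  Baseline temperature is 38.5 °C; the peak is
tracked at every step and flagged against 42 °C (denaturation), 47 °C
(cancellous bone necrosis) and 50 °C (general necrosis).

## Problem sizes and determinism

Default planning runs use 2D beam-plane slices at 0.5–1 mm spacing
(3–6 points per wavelength at 500 kHz), 26–40 settle periods and 6–10
measurement periods; 3D validation runs stay at or below ~96³ voxels.
These sizes were chosen so a full single-frequency plan with a seeded
8-candidate subsample completes in about a minute on one core while
keeping every solver-physics check inside its stated tolerance; the 2D
candidate evaluations are rankings, not absolute dosimetry.  Reports are
byte-identical across reruns of the same configuration and seed (runtime
metadata aside), and every row carries the configuration hash.

## Known limitations

- Compressional waves only; oblique incidence beyond 45° is flagged, not
  modelled.
- 2D candidate evaluation compares candidates under cylindrical
  spreading; absolute transcranial gain and FWHM differ from 3D.
- The phantom's idealised closed sphere maximises cavity reverberation
  (it refocuses reflections), the worst case for focal-contour
  extraction; the time-gated measurement addresses this.
- No thermal dose (CEM43) accumulation, no perfusion by default, no
  DICOM ingestion, no registration, no phased arrays.
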