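# Methods

`ocuvib` simulates the steady-state vibration of corneal tissue under sound
excitation and inverts measured resonance frequencies to corneal elasticity.
This note documents the model, its numerical treatment, the choices made
where the physical description is genuinely open, and the limits of what the
synthetic-data tests can show.

## Harmonic structural-acoustic model

The response at an imposed circular frequency Ω = 2πf solves

    (−Ω²[M] + iΩ[C] + [K(Ω)]) {u₁ + i u₂} = {F₁ + i F₂}

on an axisymmetric (circumferential order n = 0) finite-element mesh in the
(r, z) half-plane, z along the optical axis. `[M]` is the consistent mass
matrix, `[C]` an optional Rayleigh damping operator (zero by default), and
`[K(Ω)]` the complex, frequency-dependent stiffness. Dissipation enters
through the viscoelastic modulus, not through `[C]`.

**Viscoelasticity.** Tissue follows a Prony relaxation series; in the
frequency domain the Young's modulus becomes

    E*(f) = E · (1 − Σᵢ pᵢ / (1 + iΩTᵢ)),

with the default two-parameter series p₁ = 0.1, T₁ = 1 ms. `E` is the
*instantaneous* modulus (the convention of the commercial code whose results
this package reproduces); the relaxed long-term modulus is 0.9 E. The
imaginary part of E* sets the width of every resonance peak.

**Elements.** Solid regions use 4-node bilinear or 8-node serendipity
quadrilaterals with 2×2 / 3×3 Gauss quadrature. Near-incompressibility
(ν = 0.499) is handled by mean-dilatation B-bar: the volumetric strain
operator is replaced by its element average, which removes volumetric
locking (verified against the analytic bending-stiffness ratio between
ν = 0.49 and ν = 0.499). The humour is an acoustic pressure-formulation
fluid (Helmholtz operator; density 1000 kg m⁻³, sonic velocity 1480 m s⁻¹);
its dynamic viscosity is carried as metadata only — the acoustic model is
lossless. Fluid–structure coupling is a wetted-surface integral
R = ∫ N_u n N_p r dΓ; the coupled block system is unsymmetric and every
frequency point is solved by direct complex sparse LU (SuperLU in symmetric
pattern mode; meshes are ≲ 6000 dofs, so robustness beats iterative speed).
All axisymmetric integrals carry the weight r; the common factor 2π is
dropped consistently from every operator and load.

**Prestress.** In-plane tension stiffens transverse motion through the
standard axisymmetric initial-stress (geometric-stiffness) operator,
including the hoop term σ_θθ N_a N_b / r². The flap carries the mounting
stress (0.67 kPa, uniform in-plane) directly; it is an equilibrium state
held by the clamped rim. For the globe the default is an *equilibrated*
homogeneous initial stress: an isotropic tension of magnitude IOP is
assigned to all tissues and then relaxed to self-equilibrium by a static
solve, and the small residual field feeds the geometric stiffness. A raw
homogeneous stress is not an equilibrium state; carrying it unrelaxed
(`prestress_mode="uniform"`) tensions the cornea like a drum and makes the
natural frequencies rise by 1–4 Hz per mmHg of IOP, which contradicts the
observed near-independence of the resonances from IOP in this frequency
range; the relaxed field reproduces that near-independence while keeping
the IOP in the model. `prestress_mode="static"` (stress from a static solve
under internal IOP pressure; corneal membrane stress ≈ IOP·R/2t) is also
available and is used by the test that checks the apex moves outward under
pressurisation.

## Geometries

**Flap** — rectangle r ∈ [0, 2 mm], z ∈ [0, 120 µm], 27×2 = 54 bilinear
elements by default (a refinement factor scales both directions), rim
clamped, uniform unit-pressure drive on one face, apex probe at r = 0 on
the driven face.

**Globe** — a *half* eye globe from the scleral equator to the corneal
apex:

* cornea: spherical anterior surface (radius 6.8 mm), posterior surface
  (5.57 mm) offset to give 865 µm central thickness and ~1 mm peripheral
  thickness, diameter 10.4 mm; two through-thickness element layers carry
  independent anterior/posterior moduli (defaults 24.8 / 19.8 kPa);
* limbus: 1 mm wedge blending corneal and scleral surfaces (37.2 kPa);
* sclera: spherical shell, outer diameter 19 mm, thickness 1.0 mm (not
  given by the source parameter table; set once from porcine literature);
  elasticity 744 kPa — the parameter table prints 79.2, but the same
  study's scleral-elasticity variation calls 744 "normal", and only the
  stiff value reproduces the reported corneal-dominated dynamics (see
  "Open choices");
* humour: acoustic fluid filling the half cavity, meshed as a polar fan
  (1233 8-node elements) that shares the posterior tissue surface nodes;
  the fan centre collapses degenerate quadrilaterals at the scleral centre,
  whose interior Gauss-point Jacobians remain positive;
* boundary conditions: the equatorial scleral cross-section is fixed (the
  mounted posterior half is not modelled); a 1 mm holder ring on the outer
  sclera at a *lateral* distance of 5 mm from the apex — immediately behind
  the limbus, where a holder cup grips the globe — is fixed; the fluid is
  pressure-released (p = 0) on the cut plane, standing in for the
  compliance of the unmodelled posterior humour; u_r = 0 on the axis;
* drive: by default a rigid harmonic base motion of the mounting along the
  axis — the sound field shakes the whole mounted globe, so the consistent
  load is Ω²·(M·û) on the tissue plus ρ_f Ω²·Rᵀû on the humour. A uniform
  sound pressure on the anterior cornea is available instead
  (`drive_mode="pressure"`); it excites the same resonances but couples
  weakly to several of them at the apex probe. Absolute amplitudes are not
  physically calibrated; only peak positions and mode shapes are
  interpreted.

Element counts (80 cornea / 12 limbus / 182 sclera / 1233 fluid) follow the
reference discretisation. Keratoconus-like local weakening reduces the
modulus of corneal elements whose centroid angle (0° at the scleral
equator, 90° at the apex, about the scleral centre) falls in a chosen band.

## Response analysis

A sweep solves one harmonic system per grid point and records the apex
amplitude |u_z| and phase. Peaks are local maxima with prominence above 5%
of the global FRF maximum (configurable), refined by 3-point quadratic
interpolation; inside fitting and sensitivity loops a 5 Hz grid with local
1 Hz refinement replaces full 1 Hz sweeps (the refined peak frequencies
agree to well under 1 Hz at a fraction of the cost). Mode shapes are
classified by the number of zero crossings of Re(u_z) along the anterior
corneal arc (nodal circles) and by the scleral share of the elastic
deformation energy. Because the prominence threshold is *relative*, a very
tall fundamental resolved on a fine grid can push a marginal harmonic below
threshold; the peak-count checks therefore state the grid they use.

## Sensitivity and inversion

One-at-a-time sweeps vary a named parameter over ±20% (5 levels), track
modes across levels by an order-preserving alignment (a mode that leaves
the window is recorded as missing, never re-indexed) and report ordinary
least-squares slopes per mode. For elasticity gradients of the globe the
modes are first classified and the cornea-dominated family (scleral energy
share below one half at the nominal level) is tracked by shape — nodal
circle count and participation continuity — with the analysis window
extended to 600 Hz so the highest tracked mode stays in view across the
sweep. The inversion adjusts a single corneal
modulus (globe: anterior, posterior co-scaled) by bounded scalar
minimisation of Σ(f_sim − f_obs)² with a 13-point scan to locate the basin
(the peak-count penalty makes the objective piecewise) followed by Brent
refinement to |ΔE| < 0.05 kPa. The modulus uncertainty is the measurement's
frequency resolution divided by the local sensitivity slope of the most
responsive matched mode — one plausible reconstruction of how a 40 Hz
experimental step maps to ~30% modulus uncertainty at flap scale.

## Synthetic data

`synth` emulates the acquisition chain: forward-model apex response →
sinusoidal displacement traces (48 kHz sampling) with optional rigid
reference motion, 10% second-harmonic drive contamination and additive
Gaussian noise; FRF-level noise is multiplicative log-normal (amplitude
spectra are positive). One seed fixes all randomness. What these data do
not emulate: OCT speckle and phase noise structure, drift, lateral motion
artefacts, or amplitude calibration to sound pressure — so passing tests
demonstrate correctness of the processing chain and inversion logic, not
robustness to every artefact of real acquisitions. Amplitude extraction is
a least-squares projection on the drive tone with DC and second-harmonic
nuisance columns after integer-period truncation; on an exact
integer-period window it equals the single-bin DFT, and it is invariant to
start phase and DC offset.

## Open choices and known limitations

* **Scleral stiffness.** The source parameter table (79.2 kPa) and the
  scleral-variation study (744 kPa "normal") disagree by ~10×. With
  79.2 kPa the globe modes are sclera-dominated and corneal elasticity
  shifts the fourth mode by ~0.4 Hz/kPa — an order below the reported
  sensitivity gradients; with 744 kPa the reported corneal dominance is
  reproduced. The default is 744; both are plain config values.
* **Half-globe boundary.** The equatorial cut does not exist physically;
  clamping it and pressure-releasing the fluid is one idealisation of the
  mounted globe. It suppresses scleral band modes more than the real
  mounting may have.
* **Prony scope.** The relative modulus is applied to the full (Young's)
  stiffness; the bulk response is co-scaled through a fixed Poisson ratio.
  Whether the original model relaxed shear only is not stated.
* Geometry is not updated by the prestress deformation (small-strain,
  stress-stiffening only); materials are linear; circumferential order is
  fixed at n = 0, so non-axisymmetric (decentred-cone) behaviour is out of
  scope.
* Problem sizes: the default globe system has ≈ 5000 free dofs and solves
  at ≈ 25 ms per frequency point; a full 1 Hz sweep of 50–510 Hz takes
  ≈ 12 s and an elasticity fit a few minutes. These defaults are the
  reference discretisation; refinement studies back the reported
  convergence.
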