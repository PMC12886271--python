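# Methods

This note documents the models, numerical choices and known limitations of
`dropstress`. It is written for a user who wants to know exactly what each
number means and where the package's design was genuinely open.

## Units and conventions

All library internals are SI (m, Pa, N/m, s). The CLI and config boundary
accepts explicit unit suffixes (`um`, `kPa`, `mN/m`, `ul`, ...) through
`dropstress.units.parse_quantity`; bare numbers are taken as SI. Image
coordinates use pixel centers with the origin at the top-left, x right and
y down; physical lengths come from a per-frame `pixel_size`.

## Inclusion mechanics

The deformation model treats the droplet as an incompressible liquid
inclusion with interfacial tension γ embedded in a linear-elastic,
incompressible medium (ν = 1/2) under uniaxial far-field stress σ∞:

    b/a = (1 + 10 ε*) / (1 − 5 ε*),   ε* = (σ∞/E) / (6 + 15 γ/(E R)).

Assumptions worth keeping in mind: small-strain linear elasticity of the
medium, an initially spherical droplet, uniaxial loading, and mechanical
equilibrium (no viscous history). The law is a one-parameter family in ε*;
any two parameter sets with equal ε* predict identical shapes, which is also
how the package's tests check the implementation.

Numerical choices:

* **Validity domain.** The denominator vanishes at ε* = 1/5; the package
  raises `ModelValidityError` there instead of returning a negative or
  divergent aspect ratio. Physically, stresses that large drive the droplet
  outside the small-deformation regime anyway.
* **ν is hard-fixed at 1/2.** The closed form used here is derived for an
  incompressible medium; silently accepting other ν would produce wrong
  numbers, so any other value is rejected at construction.
* **Axis normalization.** `EllipseFit` normalizes b := max, a := min at
  construction rather than trusting caller order; the inverse model rejects
  aspect ratios below 1 rather than guessing which axis was which.
* **σ_loc uncertainty.** The default propagation perturbs the axes
  anti-correlated by one pixel (a + δ with b − δ, and vice versa) and
  reports half the spread — the convention used when the dominant error is
  contour placement at the image resolution. A first-order analytic
  propagation assuming independent axis errors
  (`local_anisotropic_stress_linearized`) is provided as a cross-check; the
  two differ by the correlation assumption, not by scale.
* The inverse of the aspect-ratio law is exact algebra
  (ε* = (r − 1)/(5r + 10)), so forward/inverse round-trips are tested at
  1e-12 relative tolerance, not at a fitting tolerance.

The local Laplace readout σ_loc = 2γ(C_b − C_a) is model-free with respect
to the medium: it only expresses the pressure-jump difference between the
points of extreme curvature of the observed ellipse. σ∞ (inclusion inverse)
and σ_loc (Laplace) answer different questions and generally differ; the
package exposes both and leaves the interpretation of in vivo loadings —
which are rarely uniaxial — to the user. For deformed ~20-µm droplets in
compressed multicellular tissue, σ_loc of a few hundred Pa is the expected
order of magnitude.

## Formulation calculators

The coverage chain converts a droplet size distribution into a minimum
lipid concentration: droplet count n = V_w/v̄ with v̄ = (π/6)·E[d³] (the
mean sphere volume, not the volume at the mean diameter); total interfacial
area from per-droplet sphere areas; moles of lipid at one head per
`area_per_lipid` (default 1 nm²); mass per oil volume. Binder (streptavidin)
concentration follows from one binder per `lipid_per_binder` (default 2000)
interfacial lipids, expressed per water volume where the binder is
dissolved.

Open choices, and what was decided:

* **Water volume fraction reference.** Φ is reported against the oil volume
  by default (50 µL/800 µL = 6.25 % for the reference batch), with the
  total volume available via `reference="total"` (5.88 %). The two
  definitions coexist in practice; the package defaults to the one that
  matches the working convention for this batch geometry and exposes the
  other explicitly rather than silently.
* **Monodisperse shortcut.** When only v̄ is known, the area uses the
  sphere of volume v̄. When a full distribution is given, the exact
  per-droplet summation is used. For a polydisperse sample the shortcut
  underestimates area (d² vs d³ weighting), which is one reason reported
  minimum concentrations should be read as order-of-magnitude design
  anchors, not calibrated values.
* **Binder molar mass.** 52,800 g/mol (streptavidin tetramer) is an
  assumption, flagged in every report and configurable; monomeric or
  conjugated binders change the mass answer proportionally.

With the defaults, the chain gives ~0.67 mg/mL lipid and ~0.30 mg/mL
binder for the reference batch — the same order as the ~0.5 and 0.2 mg/mL
working targets used in practice, whose exact arithmetic path (choice of
mean, reference volume, binder mass) is not fixed by any single convention.

## Rising-drop tensiometry

Shapes are generated by integrating the arc-length Young–Laplace system
(dx/ds = cos φ, dz/ds = sin φ, dφ/ds = 2/b0 − Δρg z/γ − sin φ/x) with
`scipy.solve_ivp` (RK45, rtol 1e-10 for standalone profiles, 1e-8 inside
the fitting loop). The apex singularity is handled by starting at
s₀ = 1e-6·b0 from the series x ≈ s, z ≈ s²/2b0, φ ≈ s/b0. Two terminal
events bound the physical meridian: x → 0 (profile closes) and φ leaving
(0, π) (the solution folds over or oscillates like a meniscus). If the
tangent angle never reaches π/4 before folding, no captive drop exists at
that tension and `DropDetachedError` is raised.

Correctness is checked three independent ways: against a fixed-step RK4
integrator at a much finer step, against quadrature of the enclosed volume,
and by a plug-back residual. The residual uses the exact integral (axial
force balance) form of the equation,
x·sinφ = ∫ x(2/b0 − Δρgz/γ) cosφ ds, rather than differentiating the
sampled φ — differentiation amplifies interpolation noise of the dense
output far above the integration error, while the integral form preserves
it; the residual is nondimensionalized by b0 and stays below 1e-8.

`fit_pendant_drop` is a standard ADSA scheme: nonlinear least squares over
(γ, b0, apex position[, tilt]) of the orthogonal distance between contour
points and the model meridian. Distances are measured by projecting each
point onto the polyline segments adjacent to its nearest model vertex —
point-to-vertex distance alone biases γ by about the sample spacing, which
was the dominant error before this change. Initialization is geometric
(apex from the lowest contour points, b0 from the apex paraboloid), with a
coarse Bond-number scan (0.02–2, geometric grid) selecting the start for a
Levenberg–Marquardt polish. Tilt is in the parameter vector but fixed to 0
by default: for apex-up contours it trades off weakly against apex position
at low Bond number and degrades γ recovery without a modelled benefit.

Degeneracy: at Bond → 0 the shape is a sphere and carries no information
about γ. After fitting, the residual of a plain circle fit (Kasa algebraic)
is compared with the ADSA residual; if the circle fits essentially as well
(within 5 % plus 0.05 px), or the fitted Bond number leaves [1e-4, 10], a
`DegenerateShapeWarning` marks γ as ill-constrained rather than reporting a
confident wrong number.

Equilibrium tensions come from γ(t) = γ_eq + (γ0 − γ_eq)e^(−t/τ) fitted by
`curve_fit` with positivity bounds and tight (1e-14) tolerances; 95 %
confidence intervals are read from the covariance. A constant series leaves
τ unidentifiable and is returned as γ_eq = γ0 = mean with an infinite CI on
τ; a fitted τ longer than the observation span triggers an extrapolation
warning.

Defaults used in synthetic tensiometry data — Δρ = 80 kg/m³ (vegetable oil
rising in water), b0 ≈ 1.5 mm, 5 µm/px — are assumptions chosen to put the
Bond number in the well-conditioned range 0.05–2, not measured values.

## Image quantification

**Sizing.** Threshold (manual or Otsu) → distance-transform watershed →
filters → resolution floor. Watershed markers are *connected plateaus* of
local maxima of the distance transform (5×5 maximum filter), not individual
peak pixels: a ridge-shaped object has one connected plateau and is kept
whole, while two touching droplets have separate maxima and are split.
Objects with area < 6 px² or circularity 4π·area/perimeter² < 0.5 are
discarded (circularities marginally above 1 from discretization are clipped
to 1), then equivalent diameters below the 0.3-µm resolution floor are set
to exactly the floor. Filtering precedes flooring, so flooring never
changes the object count. Both thresholds are configurable in their native
units (px², dimensionless, µm).

**Preprocessing.** Bleaching compensation matches each frame's histogram to
the first frame (bleaching dims monotonically, so the first frame is the
least-degraded reference); saturation then caps pixels at 10× background.
Background is the median intensity of pixels outside Otsu-detected objects
— the region used for "background" is itself a choice, so the mean is
available by flag.

**Functionalization signal.** The ring region is the set of pixels inside
the contour within `ring_width` (default 3 µm) of it, computed by a
distance transform of the contour mask; the signal is mean ring intensity
over mean outside-contour intensity. A uniform image gives exactly 1.0;
bare droplets measure ~1.1 and functionalized ones ~1.9 in practice. The
measurement refuses contours touching the frame edge and droplets smaller
than the ring.

**Ellipse fitting.** Direct algebraic conic fit (`skimage` EllipseModel)
seeds a geometric refinement minimizing true point-to-ellipse distances
(`least_squares`, LM). Manual three-point seeding is unnecessary for
synthetic and bright contours, where automatic fitting is equivalent;
axis uncertainty is set to one pixel, matching the σ_loc propagation.
Equatorial-plane selection from a z-stack takes the slice maximizing the
fitted ellipse area π·a·b.

## Synthetic data: what it emulates, and what it does not

All tests run against generators that emit a machine-readable truth record;
no test re-derives ground truth from rendered pixels.

* **Emulsion fields** draw diameters from a lognormal law moment-matched to
  the target arithmetic mean and SD (default 0.66 ± 0.37 µm, the reference
  emulsion statistics). Lognormal is the standard two-moment choice for
  positive, right-skewed sizes; the matching (σ²_ln = ln(1 + CV²)) is exact.
  Disks are rendered anti-aliased by coverage; droplets below the optical
  resolution (0.3 µm) render at the resolution size, never smaller —
  mimicking diffraction-limited image formation, and the reason the sizing
  pipeline's floor rule exists at all. A configurable fraction of droplets
  is placed deliberately touching to exercise the watershed.
* **Stressed droplets** render an ellipse whose aspect ratio comes from the
  forward inclusion model and whose cross-section preserves the undeformed
  area (a·b = R², incompressibility); the undeformed radius is defined as
  √(a·b) since the at-load radius measurement convention is otherwise
  ambiguous. An optional bright inner band of controlled contrast over
  background makes a functionalization fixture.
* **Drop contours** wrap the Young–Laplace integrator and add Gaussian
  noise along the local normal, in pixels.

Fixed seeds give bit-identical outputs. What the generators do **not**
emulate: realistic PSF blur and photon noise, z-stacks beyond a trivial
defocus, droplet crowding/occlusion, tilted or asymmetric drops, needle
reflections in tensiometry images. Passing tests therefore demonstrate
correctness of the measurement chain on idealized images with known truth —
not robustness to every artifact of real microscopy.

## Problem sizes in the test suite

The suites run at sizes chosen to make the statistical assertions
meaningful while staying lightweight: 500-droplet fields at 0.1 µm/px for
segmentation recovery (sampling SE of the mean ≈ 2 %, against a 5 %
tolerance), 20 noise seeds for pendant-drop Monte-Carlo (median error
against a 2 % tolerance), 50 seeds for ellipse and decay Monte-Carlo, and
2×10⁵ diameter draws for the mean-volume computation (SE ≈ 0.2 %).

## Known limitations

* The inclusion inverse assumes uniaxial far-field loading; in vivo
  loadings are generally not uniaxial, and then only σ_loc is meaningful.
* 2-D elliptical analysis of a 3-D droplet: the analyzed plane is the
  largest cross-section, which understates deformation if the ellipsoid's
  long axis is inclined to the imaging plane. Full 3-D surface
  reconstruction is out of scope.
* Piston force to far-field stress conversion (σ∞ = F/A) is provided as
  generic plumbing; the contact area must be supplied by the user.
* Time-dependent (viscoelastic) droplet response is not modelled; stress
  time series are quasi-static per-frame readouts.
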