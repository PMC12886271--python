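# dropstress

Design and readout toolkit for **inverted-emulsion droplet stress sensors** —
oil microdroplets (carrying a water-in-oil inner emulsion for
self-functionalization and drug release) that are injected into soft
biological material and report local mechanical stress through their shape.

It is written for experimentalists who formulate, inject and image such
sensors: soft-matter physicists and mechanobiologists who need to (i) decide
how much surfactant and binder to put in a batch, (ii) measure the
interfacial tension of a formulation by rising-drop tensiometry, (iii)
quantify emulsion micrographs, and (iv) turn an imaged droplet ellipse into
a stress, with uncertainties.

## The physics in brief

**Deformability.** A droplet of radius $R_d$ in a medium of Young modulus
$E$ deforms only if it is at least as large as the elastocapillary length
$L_{ec} = \gamma/E$; equivalently the interfacial tension must satisfy
$\gamma \lesssim E R_d$. For 10-µm droplets in soft tissue
($E = 100{-}1000$ Pa) this is the 1–10 mN/m design window.

**Forward model.** For an incompressible medium ($\nu = 1/2$), a liquid
inclusion with interfacial tension under uniaxial far-field stress
$\sigma_\infty$ takes an ellipsoidal shape with aspect ratio

$$\frac{b}{a} = \frac{1 + 10\,\epsilon^*}{1 - 5\,\epsilon^*},
\qquad
\epsilon^* = \frac{\sigma_\infty/E}{6 + 15\,\gamma/(ER)} ,$$

so all combinations of $(E, \gamma, R, \sigma_\infty)$ collapse onto a
single curve in $\epsilon^*$. The package provides the forward law, its
closed-form inverse $\sigma_\infty(b/a)$, and the validity guard
($\epsilon^* < 1/5$).

**Local readout.** Independently of the medium's constitutive law, the
Laplace balance on the fitted ellipse gives the local anisotropic stress

$$\sigma_{loc} = 2\gamma\,(\mathcal{C}_b - \mathcal{C}_a),
\qquad
\mathcal{C}_b = \frac{b}{a^2},\quad
\mathcal{C}_a = \frac{1}{2a} + \frac{a}{2b^2},$$

with $b \ge a$ the long/short semi-axes; the uncertainty is propagated by
perturbing each axis by one pixel.

**Tensiometry.** Interfacial tension is extracted from rising-drop contours
by nonlinear least squares against Young–Laplace meridians (axisymmetric
drop shape analysis), and equilibrium tensions from time series by fitting
$\gamma(t) = \gamma_{eq} + (\gamma_0 - \gamma_{eq})e^{-t/\tau}$.

## Worked example

Formulation report for the reference batch — 50 µL of water emulsified in
800 µL of oil, with a mean inner-droplet volume of 0.35 µm³:

```bash
$ dropstress design --vw 50ul --voil 800ul --mean-volume-um3 0.35
phi_percent,mean_volume_um3,n_droplets,total_area_m2,c_lipid_min_mg_per_mL,c_binder_mg_per_mL,M_binder_g_per_mol
6.25,0.35,1.429e+11,0.3431,0.6695,0.3008,52800
```

Reading: the batch is a 6.25 % water volume fraction dispersed as
~1.4×10¹¹ droplets with ~0.34 m² of water/oil interface; covering that
interface at 1 nm² per lipid head requires at least ~0.67 mg/mL of lipid
(940 g/mol) in the oil phase, and a 1:2000 binder:lipid stoichiometry
translates to ~0.30 mg/mL of streptavidin in the water phase. These are
lower bounds — not all lipid partitions at the interface.

Stress from a deformed droplet:

```bash
$ dropstress mech --aspect 1.2727 --E 1kPa --gamma 0mN/m --radius 10um
mode,E_Pa,gamma_N_per_m,R_m,aspect_ratio,epsilon_star,sigma_inf_Pa,uncertainty
inverse,1000.0,0.0,9.999999999999999e-06,1.2727,0.016665138876157295,99.99083325694377,0.0
```

An aspect ratio of 1.27 in a 1-kPa gel at negligible interfacial tension
corresponds to a far-field uniaxial stress of ~100 Pa.

Other subcommands: `tension fit-profile` / `tension fit-decay` (interfacial
tension from a contour CSV or a time series), `sizes` (inner-droplet size
distribution of a TIFF micrograph), `ring` (functionalization signal),
`deform` (ellipse fit + σ_loc from a contour CSV), and `synth` (synthetic
fixtures with ground-truth sidecars). Run `dropstress --help` for flags.

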