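# Methods

`meniscimech` is a reduced-order, coronal-plane model of the tibiofemoral
joint built to study one question: how does a uniform change in the
cross-sectional height of one meniscus alter meniscal extrusion, the
medio-lateral translation of the femur relative to the tibia, and joint
congruence?  The package deliberately replaces a patient-specific 3-D
finite-element analysis with a planar surrogate whose every ingredient is
analytic and testable.  Absolute forces and pressures are surrogate-level;
the model is built for signs, orderings and trends.

## Constitutive models

**Ligaments.**  Nearly incompressible, transversely isotropic hyperelastic
law with strain energy

    Phi = C1 (I1_bar - 3) + (1/D1) (J - 1)^2 + F2(lambda),

where `I1_bar` is the first invariant of the isochoric left Cauchy–Green
tensor, `J = det F`, and `lambda` the fiber stretch.  The fiber family obeys
the standard exponential-toe/linear recruitment law in terms of
`lambda dF2/dlambda`: zero for slack fibers (`lambda <= 1`), exponential toe
`C3 (exp(C4 (lambda - 1)) - 1)` up to the straightening stretch
`lambda_star`, then linear `C5 lambda + C6`.  `C6` is always derived from
branch continuity at `lambda_star`.  Four parameter sets (ACL, PCL, MCL,
LCL) ship as defaults.  Decisions worth recording:

* `F2` itself is needed for the energy; the toe branch integrates to an
  exponential-integral (`scipy.special.expi`) term with `F2(1) = 0` and
  value continuity at `lambda_star`.  An overflow guard caps the exponent
  argument at 700 and raises a parameter error rather than saturating.
* Fibers carry no compressive load; no smoothing is applied at
  `lambda = 1` (the kink is physical).
* The Cauchy stress is the closed-form derivative of the energy
  (isochoric Neo-Hookean deviator + volumetric pressure + rank-one fiber
  term); it is verified against central finite differences of the energy on
  random admissible deformation gradients at every run of the test suite.
* One fiber family per ligament is assumed.

**1-D ligament reduction.**  For the planar solver each ligament is a
tension-only nonlinear spring: force = insertion area x axial Cauchy stress
of the incompressible uniaxial response `2 C1 (l^2 - 1/l) + lambda dF2/dl`
at total stretch `lambda_0 * lambda`.  This is a declared approximation of
the 3-D mixed formulation.  The prestretch `lambda_0 = 1.05` is imposed by
choosing each ligament's slack length so that the stretch at the reference
configuration equals `lambda_0`; for raised-meniscus variants the femur
reference is lifted by the height increase and the slack lengths are
re-derived there, so the ligament resultant after the stretch phase matches
the intact model exactly.  Insertion areas and the planar anchor layout are
not observable from the study conditions; literature-typical values are
shipped as editable defaults (ACL 32, PCL 40, MCL 25, LCL 15 mm^2;
near-vertical collaterals at |x| = 40 mm, central cruciate-equivalents).
Force-level outputs therefore carry meaning in trends, not absolutes.

**Menisci.**  Linear, transversely isotropic about the circumferential
axis: `E_theta = 120`, `E_r = E_z = 20` MPa, `nu_rz = 0.2`,
`G_rz = 8.33` MPa (consistent with in-plane isotropy `E_r / 2(1+nu_rz)` to
0.04 %), `G_rtheta = G_ztheta = 57.7` MPa.  The 6x6 orthotropic compliance
is assembled with the reciprocal relations; the theta-coupling Poisson
ratios (0.3) are interpreted as fiber-major ratios `nu_theta_r`,
`nu_theta_z` — the only reading for which the printed set is positive
definite.  A flag (`theta_ratio_convention="as_printed"`) exposes the
minor-ratio reading, which fails the positive-definiteness check for the
shipped values and raises accordingly.

**Cartilage.**  Linear isotropic, `E = 10` MPa, `nu = 0.45`.

**Horn attachments.**  Axial springs `E A / L` per horn with the four
printed moduli (161/96.3 lateral, 179/85.3 medial MPa) and shared default
area 30 mm^2 and length 12 mm.

## Synthetic geometry

Each compartment is a circular femoral condyle (R = 20 mm) over a tibial
plateau profile, with a triangular wedge meniscus at the periphery.  The
coordinate convention is x medio-lateral (positive toward medial), y
proximal, origin at the joint centre.  Asymmetry encodes the anatomy that
drives the mechanism:

* the medial plateau is concave and closely conforming
  (curvature -0.049 mm^-1 against the condyle's 0.05);
* the lateral plateau is convex (convex-on-convex contact,
  +0.04 mm^-1) with its apex shifted 3 mm toward the intercondylar
  eminence, so lateral cartilage-cartilage contact rides the inner flank of
  the condyle;
* the wedge zones carry smaller out-of-plane depths (12 mm medial, 26 mm
  lateral) than the central cartilage-cartilage zones (40 mm), reflecting
  the partial anterior-posterior coverage of each plateau by its meniscus,
  larger laterally.

**Calibration.**  The wedge widths are not free parameters: they are
derived from the intact peripheral heights (`h_L = 4.6`, `h_M = 4.2` mm)
and the intact average slope angles (`beta_L = 32.7`, `beta_M = 23.9` deg),
the study's only printed geometric observables, via
`width = h / tan(beta)`.  Each wedge is positioned so its face is tangent
to the condyle where the surface slopes match (`R sin(beta)` off-centre).
Height variants change `h` only; width and placement stay fixed, so the
slope angle moves with the height.  The nine variants apply the exact
perturbations `+-0.9 / +-1.8` mm medially and `+-1.0 / +-2.0` mm laterally
(about 21.5 % and 43 % of the intact heights).

The crescent is reduced to `n_sections = 7` independent cross-sections per
meniscus for angle averaging; a per-section height profile is supported
(uniform by default), in which case the average angle is the arithmetic
mean of the section angles.  The slope is measured on the superior
(femoral-facing) wedge surface.

## Contact equilibrium

Degrees of freedom: femur medio-lateral translation `u`, axial translation
`u_y`, varus/valgus rotation `phi_z`; plus one radial outward shift `w` per
meniscus.  External/internal rotation is out of plane and held at zero; the
bones are rigid.

Contact is a frictionless unilateral elastic (Winkler) foundation evaluated
on ~0.4 mm stations.  Station pressure is `k * max(0, -gap)` with the gap
measured vertically; the foundation constant per zone is the series
combination of the confined (oedometric) layer moduli: two cartilage layers
for cartilage-cartilage contact, plus the meniscus's constrained axial
modulus (from the inverted compliance matrix) over half the wedge height
for the wedge face.  The effective layer thickness (4.25 mm) lumps the
cartilage and the adjacent soft-tissue compliance of the real joint into
the foundation; it controls how gradually load redistributes between the
wedge and the uncovered cartilage and was fixed once for the shipped joint.
For a face inclined at `beta` this vertical-gap formulation transmits a
lateral force equal to the vertical force times `tan(beta)` — exactly the
frictionless wedge decomposition `N sin(beta)` — which is the engine of
both meniscal extrusion and the medio-lateral imbalance.

Each meniscus is restrained radially by a hoop-tension ring stiffness
(thin-ring formula `E_theta A_c / R^2` integrated over a 30 mm engaged
arc, ring radius 32 mm) plus its horn attachments (axial stiffness
projected radially with factor 0.5).  At equilibrium the extrusion force
equals `k_w * w` identically.

**Numerics.**  The residual is the analytic gradient of the total
potential (foundation energy + ligament spring energy + ring restraint -
load work), so force balance, the CM-L constraint reaction and the
verification oracle are all consistent by construction.  Newton iteration
with a finite-difference Jacobian, backtracking line search on the energy,
Levenberg damping for indefinite tangents and a 0.5 mm / 0.02 rad step cap
(grazing contact makes the tangent nearly singular); the load ramps in 10
increments after a zero-load (post-prestretch) baseline solve.  Residual
tolerance `1e-8 x` applied load (absolute floor 1e-9 N); the moment
component is scaled by a 30 mm lever for the convergence norm.  The
unilateral kink is smoothed over a C1 band of
`stabilization_factor x 0.1 mm = 0.01 mm`.  Exactly-zero gaps count as
contact at zero pressure.  The wedge support surface is extended linearly
below the inner rim and capped flat at the peripheral height so the energy
stays continuous in `w`.  In CM-L mode `u` is removed from the unknowns and
the reaction `F_M-L = -dPi/du` is reported (positive = the joint pushes the
femur medially).  The pipeline contains no randomness.

**Verification oracle.**  An independent derivative-free minimiser of the
same potential (cyclic coordinate grid search with bracket shrinking,
polished by a Nelder–Mead simplex) reproduces the Newton kinematics within
the grid resolution on randomized joints; this is a standing test.

## Measured values

* `u`: medio-lateral displacement of the femur relative to the tibia at the
  joint centre, positive toward medial, at the target load.
* `w_M`, `w_L`: radial outward shift of each meniscus relative to the
  tibia, reported as loaded-minus-unloaded displacement (the unloaded state
  is the prestretched zero-load equilibrium).  The radial component is
  used, not the displacement magnitude.
* `F_M`, `F_L`: extrusion forces — the radially outward components of the
  contact resultants on each meniscus, summed over sections; outward means
  medial for the medial meniscus and lateral for the lateral one.
* `F_M-L`: the CM-L constraint reaction (zero in free mode).
* `CM = F / p0` per compartment: resultant tibial-side contact force over
  peak station pressure (no smoothing of the peak), with the total contact
  area as a companion measure.  `CM` equals the contact area for a uniform
  pressure field and is bounded by it in general.

## The experiment and what passing means

`run_suite` replays 9 variants x {free, CM-L} x 1000 N (ramped),
deterministically, and `trend_report` evaluates the qualitative claims: the
free-mode `u` ordering across each variant family, co-monotonicity
(Spearman rho = 1) of `F_M-L` with `beta_L - beta_M`, strict growth of the
constrained external shift with the height change, unloading of a lowered
meniscus (contact force and area), loss of cartilage-cartilage area under a
raised meniscus, and maximal extrusion forces for the raised variants.
With the shipped calibration all checks pass; the intact joint yields
`u ≈ 0.51 mm` and `F_M-L ≈ 105 N`, the same sign and scale as the
tabulated reference values (0.392 mm, 79.6 N).

The synthetic geometry emulates a two-compartment coronal cross-section
with controllable wedge heights; it does not emulate patient-specific 3-D
surfaces, sagittal-plane geometry, menisco-capsular attachments, flexion,
anterior-posterior translation or internal rotation, friction, dynamic or
poro/viscoelastic effects.  Passing trends therefore demonstrate that the
proposed mechanism (wedge slope imbalance driving extrusion and
medio-lateral translation) is reproduced by a minimal mechanical model
under the study's material parameters — not that the surrogate predicts
absolute in-vivo forces, pressures or contact areas.  Absolute
contact-pressure validation is out of scope by design.

## Known limitations

* The elastic-foundation contact is the largest declared approximation;
  pressures are station-wise and not comparable in magnitude to 3-D FEM.
* The femur-side lateral force at a station uses the condyle surface slope
  while the meniscus-side radial force uses the wedge slope; both are exact
  gradients of the same potential, but interface force pairs are not
  point-wise reciprocal (they differ by the local slope mismatch).
* The 1-D ligament reduction ignores fiber-matrix shear coupling and
  insertion-site mechanics.
* The per-variant slope angles follow `atan(h / width)` and deviate from
  the tabulated per-variant averages by up to ~2 deg at the extremes (the
  tabulated values come from anatomic surfaces, not a triangular wedge);
  the intact angles match by construction.
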