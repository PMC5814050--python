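# meniscimech

A reduced-order, coronal-plane model of the tibiofemoral joint for studying
how changes in the cross-sectional height of a meniscus drive **meniscal
extrusion** and **medio-lateral knee translation**.

Menisci are wedge-shaped fibrocartilage rings between the femoral condyles
and the tibial plateau.  Under compression, the inclined femoral-facing face
of each wedge (slope angle β) converts axial load into a radially outward
*extrusion force* ≈ N sin β, restrained by circumferential hoop tension and
the horn attachments.  Because the lateral and medial wedges generally have
different slopes, the two compartments push the femur sideways with
different strengths: the net medio-lateral force scales with
β̄\_L − β̄\_M, translating the femur (u > 0 toward medial) or — if the
relative bone motion is constrained (CM-L mode) — appearing as a constraint
force F\_M-L.  Degenerative changes in meniscus shape can therefore alter
both extrusion and joint stability without any tear.

The package provides, for researchers in musculoskeletal biomechanics:

* fiber-reinforced transversely isotropic hyperelastic **ligament laws**
  (Neo-Hookean matrix + exponential-toe/linear fiber recruitment with the
  continuity constant C₆ derived, volumetric penalty (1/D₁)(J−1)²), with
  Cauchy stress verified against a finite-difference energy gradient;
* transversely isotropic **meniscus elasticity** and horn-attachment
  springs;
* a parametric **synthetic joint geometry** (conforming medial compartment,
  convex-on-convex lateral compartment, wedge menisci with controllable
  heights), calibrated so the intact average slope angles are
  β̄\_L = 32.7°, β̄\_M = 23.9°;
* a frictionless elastic-foundation **contact equilibrium solver** (rigid
  bones; DOFs: u, u\_y, varus/valgus φ\_z, plus a radial shift w per
  meniscus) with an independent energy-minimisation oracle;
* the **outcome metrics**: external shifts w\_M/w\_L, extrusion forces
  F\_M/F\_L, constraint force F\_M-L, and the congruence measure
  CM = F/p₀ (resultant contact force over peak pressure);
* a deterministic **virtual experiment**: nine meniscus-height variants
  (Δh\_M = ±0.9/±1.8 mm, Δh\_L = ±1.0/±2.0 mm) × {free, CM-L} × 1000 N,
  with a trend report over the expected qualitative findings.

## Worked example

Solve one variant from the command line:

```bash
menisci-mech solve --variant LMH++ --mode free --load 1000
```

```json
{
  "variant": "LMH++",
  "mode": "free",
  "load_N": 1000.0,
  "u_mm": 1.4710968914551088,
  "w_medial_mm": 0.30966804632064165,
  "w_lateral_mm": 0.2915131563951461,
  "F_ML_N": 0.0,
  "extrusion_medial_N": 163.22028576097802,
  "extrusion_lateral_N": 159.4318621712139,
  "residual_norm_N": 1.5297190669727456e-06
}
```

Raising the lateral meniscus by 2 mm steepens its wedge
(β̄\_L: 32.7° → 42.6°), so the lateral compartment pushes the femur
medially: u = +1.47 mm, the largest translation in the suite.  Or run the
whole experiment from Python:

```python
import meniscimech as mm

table = mm.run_suite(mm.ExperimentPlan(variants=("Intact", "MMH--", "LMH++")))
print(table[["model", "mode", "beta_diff", "F_ML", "u", "w_M", "w_L",
             "F_M", "F_L"]].round(3))
```

```
 model mode  beta_diff    F_ML     u   w_M   w_L     F_M     F_L
Intact free      8.800   0.000 0.508 0.107 0.088 129.220 122.276
Intact  cml      8.800 104.572 0.000 0.069 0.183  99.248 186.142
 MMH-- free     18.490   0.000 1.156 0.070 0.034  48.566  48.941
 MMH--  cml     18.490 189.357 0.000 0.031 0.184  20.109 185.315
 LMH++ free     18.749   0.000 1.471 0.310 0.292 163.220 159.432
 LMH++  cml     18.749 235.975 0.000 0.142 0.690  84.844 359.440
```

Reading the table: the intact joint translates u = 0.51 mm medially under
1000 N because β̄\_L > β̄\_M; holding u = 0 instead requires
F\_M-L ≈ 105 N.  Flattening the medial meniscus (MMH--) widens the angle
gap and increases both u and F\_M-L while the flattened wedge unloads
(F\_M drops from 129 N to 49 N).  Raising the lateral meniscus (LMH++)
produces the largest translation and, in CM-L mode, the largest lateral
extrusion force (359 N) and external shift (w\_L = 0.69 mm).  The full
9-variant suite with the trend report runs via

```bash
menisci-mech sweep --out results/
```

which writes `outcome_table.csv`, `trend_report.json` and a hash manifest.
Other subcommands: `material-check` (constitutive self-checks),
`geometry render` (station profiles as CSV), `report` (re-evaluate trends
on a saved table).  A single YAML config (`--config`) overrides any
geometry, material, solver or experiment default; see
`meniscimech.default_config()`.

## Scope

Planar two-compartment statics only: no patient imaging, no 3-D mesh
export, no friction, flexion, a-p translation or internal rotation, no
visco-/poroelasticity.  Absolute forces, pressures and areas are
surrogate-level; the model is built to reproduce signs, orderings and
trends (see `docs/methods.md`).
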