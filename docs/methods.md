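# Methods

`calvasim` predicts calvarial growth after three corrective operations for
sagittal craniosynostosis — spring-assisted cranioplasty with two or three
springs (SAC2/SAC3) and a 50 mm modified strip craniotomy (MSC) — with a
quasi-static finite-element pipeline on a fully synthetic, parametric infant
calvaria. This note records the model, its assumptions, the numerical
choices, and what the synthetic geometry does and does not represent.

## Synthetic calvaria

The skull is built analytically, not from imaging:

- **Shape.** Horizontal cross-sections are superellipses
  `|x/a|^p + |y/b|^p = 1`; the exponent `p` is solved at build time so the
  outer midplane outline matches the target head circumference (an ellipse
  with axes 137.2 × 108.1 mm has perimeter ≈ 388 mm, ~10 % short of the
  430.6 mm head circumference of a real scaphocephalic head, so `p > 2` is
  required; the default solve gives `p ≈ 4.1`). The vertical profile is an
  elliptical dome above the widest plane, continued below by a flattened
  basal dish (`base_flatten`, default 0.4). An optional vertical-profile
  exponent steepens the side walls.
- **Inferior boundary.** The shell is *open* between the vault rim and a
  small basilar cap: an annular band of the dish is removed, leaving the
  cap (which carries the foramen magnum constraint) structurally detached
  from the vault. A calvaria segmented from CT has exactly this free lower
  edge, and it is mechanically essential — with a closed, progressively
  ossifying shell the late load steps have no compliant escape and the
  volume targets become elastically unreachable, while the open boundary
  lets growth proceed into the cranial fossae. The retained sub-equatorial
  band is the compliant synchondrosis ring (suture-grade 30 MPa, never
  ossifying), with two bony islands: the supraorbital/nasal wedge that
  carries the nasal-ridge constraint and the basilar occiput around the
  foramen (soft tissue directly against an all-DOF constraint patch
  crushes numerically and is anatomically wrong anyway).
- **Dimensions.** Outer length and width are exact by construction (the
  landmark nodes — glabella, opisthocranion, euryons — are generator grid
  points at the analytic extremes). The dome height is solved *exactly* from
  the target intracranial volume: the parametric mesh volume is degree-1
  homogeneous in each semi-axis, so the discrete ICV volume equals 659.9 ml
  to round-off at any resolution.
- **Meshing.** A latitude–longitude surface grid is extruded into wedges and
  split into conforming tetrahedra (smallest-global-index diagonal rule).
  The ICV is a separate tetrahedral ball whose outer surface triangulates
  the same smooth interface as the inner table at coarser resolution; the
  two bodies share no nodes and interact only through contact. Default desk
  resolution: ≈ 12 000 tetrahedra (≈ 7.8 mm elements), inside the 5k–500k
  window the pipeline accepts.
- **Regions.** Bone plates (frontal, parietal, temporal, occipital),
  patent sutures (coronal, lambdoid, squamosal, metopic), the fused sagittal
  suture, and the anterior fontanelle are labeled by analytic bands on the
  shell (default band width 2 mm; thin bands capture one element row, so the
  effective width is about one element). The squamosal band continues around
  the full vault perimeter: in the infant the vault plates join the cranial
  base through patent sutures and synchondroses, and this compliant ring is
  what lets the plates hinge. An optional posterior fontanelle patch at
  lambda is off by default.
- **Thickness.** 1.0 mm over the vault, graded to 3× at the basal pole
  (the real cranial base is much thicker than the infant vault, and flat
  1 mm basal elements are poorly conditioned); one quadratic element
  through the shell. Infant parietal bone at 4 months is of order 1 mm;
  within the anatomically plausible 0.7–2 mm range the vault value was
  fixed once by matching the documented in-situ spring release response of
  the reference model, the same release-widening calibration that model
  itself used to fix its tissue stiffnesses.

What the synthetic skull does **not** reproduce: patient-specific plate
outlines and suture tortuosity, regional thickness variation, the facial
skeleton and true skull base, CSF spaces, and any imaging-derived asymmetry.
Tests passing on this geometry demonstrate the mechanics, bookkeeping and
measurement pipeline, not patient-level predictive accuracy.

## Materials

Linear isotropic elasticity throughout (mm–N–MPa units):

| tissue | E (MPa) | ν |
|---|---|---|
| bone plates, fused sagittal | 421 | 0.3 |
| patent sutures, fontanelle | 30 | 0.3 |
| basal synchondrosis ring | 30 | 0.3 |
| craniotomy tissue | 0.3 | 0.1 |
| intracranial volume (ICV) | 10 | 0.1 |

Bone stiffens by 125 MPa per simulated month, newly formed bone by
100 MPa per month from its tissue's prior modulus; the ICV and the
synchondrosis ring never ramp.

## Virtual surgery and springs

SAC relabels a nominal 1 mm midline strip from the anterior fontanelle to
the lambdoid suture as craniotomy tissue (at desk resolution the captured
element row is ≈ one element wide, comparable to the ~5 mm gap present at
spring insertion in the operated model); MSC relabels a 50 mm vertex strip
between coronal and lambdoid. Spring legs attach 15 mm apart across the
craniotomy (5 mm of bone either side plus the gap), each leg anchored to an
outer-table triangle by barycentric weights and extended through the
thickness column, so the insertion leg-to-leg distance is exact up to
surface discretization.

Springs are Hookean with stiffness `K = f/Δx = 8 N / 85 mm` from the crimp
measurement (100 mm free length crimped to 15 mm) and force
`f = K (L0 − d)`. In the solver they enter as follower force pairs along
the line of the leg anchors; the force magnitude is converged by fixed-point
iteration (the spring's own ~0.1 N/mm stiffness is negligible against the
calvaria, so no tangent term is kept). A spring that would go compressive
(opening beyond free length) is clamped to zero force by default. Removal
fixes the force at exactly zero.

## Finite elements, contact, growth

- **Elements.** Straight-sided 10-node tetrahedra (4-point Gauss) for the
  shell, 4-node tetrahedra for the ICV. Quadratic shell elements are not
  optional refinement: a 1 mm shell bent at ~8 mm element size locks to
  ~20 % of its true bending compliance with linear tetrahedra (the package's
  cantilever oracle reproduces 95 % of the analytic tip deflection with
  TET10). The ICV is compression-dominated and stays linear. Midside nodes
  are generated internally; all public indices are corner-node indices.
- **Constraints.** Foramen magnum ring and nasal ridge patch fixed in all
  degrees of freedom; additionally the ICV nodes at its basal outlet are
  fixed, since a purely contact-coupled ICV would otherwise have rigid-body
  modes (physically, the brainstem tether).
- **Contact.** Node-to-triangle penalty contact from ICV surface nodes onto
  inner-table facets: normal stiffness 50 N/mm per contact node, penetration
  tolerance 0.5 mm (the penalty is escalated ×4 until the maximum
  penetration is inside tolerance), friction coefficient 0.1 enforced by a
  tangential penalty capped at μ·N by secant iteration, starting from zero
  so an unloaded interface slides freely. The as-built chord offsets between
  the two discretizations of the same smooth interface are recorded at
  generation time and subtracted from all gaps, so the bodies start exactly
  "in contact" with zero force.
- **Growth.** Isotropic stress-free eigenstrain (thermal-expansion analogy)
  on the ICV. Each load step's eigenstrain is calibrated by scalar secant
  iteration (free-expansion estimate `(V*/V)^{1/3} − 1` as the first guess,
  with a trust region against tiny secant slopes on a stiffening shell)
  until the deformed ICV volume is within 0.5 % of the step target; each
  evaluation is a full contact solve. Steps larger than ~12 % volume gain
  are sub-stepped with a geometry update in between (the increment shrinks
  adaptively whenever an update would invert an element), which keeps every
  linear solve in the small-strain regime — the geometry-update-per-interval
  strategy replaces remeshing. After each update, residual ICV/inner-table
  interpenetration (bounded by the 0.5 mm tolerance per solve) is removed
  by projecting the penetrating nodes back to the master surface; whatever
  projection would invert elements becomes a contact reference offset
  instead (adjust-to-touch), so the penalty never fights baked-in overlap.
- **Solver.** Sparse LU (SuperLU, MMD ordering, symmetric mode) on the
  constrained system (~43 k DOF at default resolution). Within a solve the
  factorization is reused across right-hand-side-only iterations (spring
  force updates); the contact system is refactorized only when the active
  set, friction caps or penalty scale change materially, with a hard cap of
  4 factorizations per solve.

## Growth schedule and ossification

Ages are mapped to target ICV volumes by piecewise-linear interpolation of
an anchor table: SAC (4 mo, 659.9 ml) → (9 mo, 829.5 ml) → (36 mo, 1240 ml)
in five steps at ages 9/15/22/29/36 with spring removal after the 9-month
report; MSC adds (12 mo, 1007 ml) and ends (60 mo, 1376 ml) in six steps at
ages 9/12/24/36/48/60. The release is a separate zero-growth solve before
the first step, so the insertion → release opening is observable on its own.

Ossification fronts advance from the bone–suture and bone–craniotomy
linings at 0.2 mm/month (coronal, lambdoid, squamosal) and 10.8 mm/month
(craniotomy healing). An element converts when the cumulative front travel
of its region reaches its distance from the lining; that distance is the
Euclidean centroid distance to the nearest ossified element minus half the
local element size (centroid-graph path lengths were tried and rejected:
their lattice tortuosity overestimates travel by ~1.9×). Distances are
first measured on the configuration current at the region's activation
(after surgery and release, so the surgical widening is included) and are
only ever raised when later deformation stretches the region — healing
cannot gain ground from a widening defect, but sub-element progress is never
forfeited, which keeps n one-month calls identical to one n-month call.
The metopic suture and anterior fontanelle do not heal by front propagation;
they are prescribed fully formed at 24 months.

A consequence worth stating plainly: at 10.8 mm/month the craniotomy heals
completely well before the 9-month report for *both* techniques. The SAC
strip (≈ 7–12 mm after release) closes within a month of healing onset, in
line with the reported complete SAC closure at 9 months; but a 50 mm MSC
defect needs only ≈ 25 mm of bilateral advance, about 2.3 months, so the
reported MSC patency at 9 months cannot be reproduced by any front starting
at surgery and advancing 10.8 mm/month — growth-induced widening (a few mm
per month at most) cannot outrun a 10.8 mm/month front. The package applies
the stated rate faithfully and reports MSC closure accordingly; the
corresponding acceptance check is expected to fail and is left failing.

## Measurements

Length is glabella–opisthocranion, width euryon–euryon (landmark nodes
tracked through deformation). Head circumference is the perimeter of the
convex outline of the outer table projected onto the axial plane through
the glabella spanned by the length and euryon axes — a tape-measure
definition; plane-sectioning the faceted surface near its equatorial edge
ring proved numerically fragile at desk resolution. The cephalic index is
always recomputed as 100 × width / length; printed reference indices appear
truncated rather than rounded in places, so comparisons use ±0.1.
ICV volume is the signed-tetrahedra sum over ICV elements. Spring opening
is the distance between the weighted leg attachment points. Distance maps
between surfaces are signed nearest-point distances (positive outside the
reference). Contact pressure is the nodal normal force over the tributary
area, averaged per face, summarized per anatomical region (anterior,
posterior, left/right mediolateral, vertex).

## Release response and model limits

With the printed moduli, an equilibrium force balance bounds what two 8 N
springs can do: stretching a bonded soft strip and shearing 30 MPa suture
bands by several millimetres requires forces an order of magnitude above
16 N unless the deformation localizes at sub-millimetre scale, which a
~7.8 mm mesh cannot and a desk-scale mesh should not pretend to resolve.
The model's converged release response opens the anterior spring to
≈ 16–17 mm (reference prediction 19.5 mm) and widens the craniotomy by
≈ 1.5–2 mm on average along the strip (reference ≈ 5 mm, which a static
analysis of the bonded strip shows must refer to the at-spring opening of a
locally resolved model rather than a uniform mean). These two comparisons
are therefore reported as-is and their strict-tolerance checks left red;
the volume targeting, ossification bookkeeping, spring parameterization and
craniometric results are quantitative.

## Determinism

Everything is deterministic for a fixed configuration: the generator is
seed-stable (bit-identical reruns), the solvers are direct, and optional
surface jitter (off by default) is the only stochastic element.
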