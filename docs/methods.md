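# Methods

`spinecorr` simulates the surgical correction of a spinal deformity with
posterior pedicle-screw/rod instrumentation on a patient-specific (here:
synthetic parametric) lumbar spine model, and reports the mechanical cost of
the correction: screw–bone interface forces, rod internal actions, and the
difference between the planned and the mechanically achieved vertebral
alignment.  This note documents the model, its assumptions, the defaults,
and the known limitations.

Units are mm / N / MPa throughout (consistent: MPa·mm² = N).  The global
anatomical frame is X = anterior, Y = left, Z = cranial.  Vertebral
rotations are reported as intrinsic Y–X–Z angles (sagittal, coronal, axial),
a convention this package fixes because planar angles alone do not define an
extraction order.

## Synthetic spine fixtures

The generator replaces a radiographic 3-D reconstruction front-end.  A
vertebra is a union of conforming block meshes on a structured grid: an
octagonal prismatic body (elliptical cell mask), a solid posterior block
standing in for pedicles and lamina, a spinous bar, and four lofted
articular processes whose tip faces are the facet contact patches.  All
sub-blocks share grid planes, so the six-tetrahedra split of each hexahedral
cell produces one conforming tet mesh whose boundary is a closed genus-0
surface.  Two deliberate departures from anatomy:

* the vertebral canal is omitted (a posterior ring would make the surface
  genus 1; every downstream operation keys on labeled region sets, not on
  surface realism);
* facet joints articulate tip-to-tip with a craniocaudal contact normal,
  rather than via near-sagittal facet planes.

Cells on the `y < 0` side of the midplane use the y-mirrored tet split
pattern (the two patterns conform across the midplane), so bilaterally
symmetric fixtures produce exactly mirror-symmetric meshes — the basis of
the left/right symmetry checks.

Region sets (endplates, pedicles, posterior elements, facet patches,
ligament insertions) and landmarks (body center, spinous tip, pedicle entry
points) are identified by construction and carried as node-index sets, the
same mechanism a template-morphing reconstruction would use; imported
surfaces (STL/PLY/OFF + JSON sidecar) use nearest-node transfer when
coarsened.

Multi-level fixtures stack vertebrae with a configurable unloaded disk gap
(default 10 mm).  An anterolisthesis is realized as a rigid anterior
translation of every vertebra cranial to the slipped junction, applied along
the caudal vertebra's anteroposterior axis and compensated so the
landmark-based slip measurement returns exactly the configured value.
Coronal/axial asymmetry totals are distributed linearly across levels,
rotating each vertebra about its body-center landmark.  The benchmark
fixture is L2–L5 with a 14 mm slip at L3–L4 and 6°/3° coronal/axial
asymmetry.

Articular-process tips are junction-adapted: the inferior tips of the
cranial vertebra sit exactly one joint clearance (0.4 mm) along the facet
normal from the caudal superior tips, *plus* the in-plane component of the
junction slip.  At a slipped junction the facets are therefore subluxed in
the assembled state and realign when the listhesis is reduced — without
this, reduction would dislocate the capsule springs and load the
instrumentation with spurious capsular tension.

## Soft tissues

**Disks.** A disk is a hex-loft between the two facing endplate node grids
(three cell layers by default), split with the same mirrored six-tet rule so
it conforms exactly to the vertebral boundary faces; its end layers weld
onto the vertebra nodes (coordinate welding at 1e-6 mm).  Elements whose
centroid falls inside a central cylinder are labeled nucleus pulposus; the
cylinder radius is solved on the sorted element-centroid radii so the
nucleus element volume is 50% of the disk volume (±2% at the default
discretization).  Ground-substance moduli: annulus 4.2 MPa / ν 0.45,
nucleus 1 MPa / ν 0.499; the "soft" (unstable) disk halves the annulus
ground and fiber stiffness.

**Annulus fibers.** Tension-only linear springs (modulus 25 MPa healthy,
12.5 MPa soft) criss-crossing the annulus wall in two balanced families.
Candidate segments connect perimeter nodes across ring/circumferential
offsets; a deterministic greedy mix of the best candidates above and below
the target keeps the mean absolute inclination to the axial plane at 30°
(±2° from discretization).  On mirror-symmetric disks the minus family is
the literal mirror image of the plus family.  Effective fiber
cross-sections are apportioned so the family total equals 16% of the
annulus horizontal cross-section — a modeling choice, configurable.

**Ligaments.** Six groups of tension-only springs per junction: ALL, PLL,
LF, ISL with three springs each, SSL with one, and the capsular ligament
with twelve per facet joint following the capsule border (the three node
rings of each articular process).  Reference lengths are the assembled
distances, so the assembled state is stress-free.  The default
force–deflection curves are *calibration stand-ins*: a 0.5 mm low-stiffness
toe followed by a linear region (per-spring stiffnesses 4–10 N/mm, group
totals in the range of published lumbar segment data); only their
tension-only, toe-then-linear shape is fixed.  All curves are configurable
per group.

**Facet contacts.** Frictionless node-to-node gap elements between the
facet tip patches, matched one-to-one by nearest neighbour, with the
construction facet normal as gap direction and exactly 0.4 mm unloaded
clearance.  Contact is compression-only and resolved as an active set of
equality constraints (exact complementarity, no penetration beyond solver
tolerance).

## Bone materials

All bony tissue is linear isotropic.  Element zones follow the proximity
rule: each element takes the zone of the labeled surface node nearest its
centroid (ties within 1e-12 mm go to the lowest node index — note that on
structured meshes with systematic ties this makes the assignment depend on
node numbering; in generic position it does not).  Body and pedicle
elements owning at least one boundary face form the one-element cortical
shell (12000 MPa / 0.3); deeper elements are trabecular (200 MPa / 0.315);
lamina, spinous and articular processes carry a single posterior-elements
material (3500 MPa / 0.25).  The one-element shell is an acknowledged
approximation: no fixed cortical thickness is enforced.

## Instrumentation

Screws are monoaxial (head rigid with shaft).  Instead of boolean-carving
screw solids out of the bone and meshing them, a screw is a rigid body whose
head reference node (6 DOF) is kinematically coupled to every vertebra node
within a capture radius of the shaft segment.  This is equivalent at the
resultant-force level reported here, keeps the bone mesh identical across
correction strategies, and deliberately gives up thread-level bone stress.
Defaults: length 45 mm, diameter 6 mm, 15° medial inclination from the
posterior pedicle entry landmark, capture radius 1.25 × diameter (a quarter
more than the shaft so the captured cloud spans at least one node layer of
the coarse mesh in every direction).  Capture sets of the two screws of one
vertebra are made disjoint (nearest shaft wins; equidistant midline nodes
are excluded from both) because shared followers would make the coupling
constraint rows linearly dependent.

Rods are interpolating cubic splines (chord-length parameter, natural ends)
through the *planned* screw-head positions, meshed into 2-node
Euler–Bernoulli beams at equal arc-length stations (24 elements/rod
default).  Section: circular, diameter 5.5 mm, E = 110000 MPa, ν = 0.3
(titanium alloy) — configurable.  Each selected screw is tied (rigid 6-DOF
constraint with lever arm, engaged at the step-ii state) to its nearest rod
node.

## Finite-element core and the three-step maneuver

Element technology: linear tet4 solids (small strain, total formulation),
linear space beams, tension-only springs evaluated on the current geometry
(exact large-displacement direction update), node-to-node gaps.  The
correction maneuvers of the benchmark are purely translational; rigid
translations produce no strain in the linear solids, and the remaining
rotations stay below a few degrees, so geometric nonlinearity is carried
where it matters (springs and contact) while solids and beams stay linear.
Constraints — supports, prescribed motions, screw couplings, screw–rod
ties, active gaps — are enforced with Lagrange multipliers; the multipliers
*are* the reaction and interface forces used by the postprocessor.  Newton
iteration with 10 load increments per step (default), residual tolerance
max(1e-6 × reference force, 1e-4 N); the contact active set is updated
inside each increment.  The solver is deterministic.

Steps:

1. **Impose correction** — rods (already in planned shape) fixed and
   unloaded; screw heads driven by prescribed 6-DOF displacements to their
   planned positions; the spine is strained.
2. **Couple and release** — screw–rod ties are engaged at the current
   relative positions, head prescriptions removed (their reactions ramped
   down as external forces), and the spine's strain energy partially
   redistributes into the rods.  The caudal end node of each rod stays
   fully fixed through steps ii–iii: this both resolves the ambiguity of
   the original constraint description and removes the global rigid modes.
3. **External load** (optional) — a force/moment resultant is realized as
   the minimum-norm nodal force distribution over a chosen endplate, with
   couplings active.

Interface force convention: the reported screw force is the coupling
resultant *on the vertebra side*; its projection on the outward shaft axis
(posterior) is the pull-out component, positive = pull-out.  With this
convention the reduced (posteriorly translated) vertebra's screws are
loaded in pull-out, as expected for a listhesis reduction.

Rod internal actions are the beam-section resultants (force/moment exerted
by the cranial part on the caudal part) expressed in the rod frame: tangent
plus the global anteroposterior and laterolateral directions projected onto
the section plane — this makes "anteroposterior shear" well defined on
curved rods.

## Benchmark suite and problem sizes

The six configurations combine partial (half-slip) or complete reduction —
a pure posterior translation of L2+L3 — with a healthy, softened, or
removed L3–L4 disk (discectomy also removes ALL and PLL at that level and
adds no endplate contact).  The assembled coarse model has ≈1100 nodes,
≈3800 tetrahedra, ≈470 springs, 24 gaps, 8 screws, two 24-element rods —
about 3700 DOF — chosen so a configuration solves in a few seconds and the
whole suite in well under a minute on one core.

What the synthetic benchmark does and does not show: the load *orderings*
(complete ≥ partial, healthy ≥ soft ≥ discectomy), the pull-out direction
at the reduced vertebra, the dominance of anteroposterior shear at the
reduction level, the near-exact realization of the planned correction, and
bilateral symmetry are all properties of the mechanics and transfer to real
geometry.  Absolute force magnitudes depend on the stand-in ligament curves
and the simplified geometry; they are plausible in scale (hundreds of N)
but are not patient predictions.  One pattern from real-geometry studies
does not reproduce here: with a straight stack and unstrained adjacent
disks, the bending moment ramped by the reduction shear peaks inside the
reduction-level rod segment rather than at adjacent levels;
flexion–extension remains the dominant moment component in every loaded
segment.

## Numerical choices and degenerate inputs

* Coordinate welding at 1e-6 mm joins vertebra/disk/ligament endpoints.
* Nucleus sizing solves the discrete radius exactly (midpoint between the
  bounding element-centroid radii); fractions 0 and 1 are honored.
* Tension-only springs contribute zero force *and* zero stiffness when
  slack; models must not rely on slack springs for stability (the solver
  reports a singular system otherwise).
* Gap elements: activation on penetration < 1e-9 mm, release on tensile
  multiplier; complementarity holds to 1e-6 N·mm.
* Mirror-symmetry checks compare left/right fields at 1% of the peak value
  of the same unit class; components that are themselves near zero sit at
  solver-tolerance noise.
* Surface coarsening is a guarded midpoint edge-collapse with a cumulative
  volume budget of 0.4% — the volume contract always holds, the target edge
  length is best-effort.  Refinement is exact midpoint subdivision.
* Delaunay tetrahedralization is exact for convex surfaces; non-convex
  inputs are containment-filtered and the boundary is only approximately
  recovered (the synthetic pipeline never relies on this path).

## Known limitations

No rib cage, polyaxial screws, hooks, osteotomies or interbody devices; no
bone failure criterion or thread-level screw mechanics; no viscoelastic or
osmotic disk behaviour; facet orientation simplified as described; ligament
curves are stand-ins; vertebral strains are small-strain linear.  Validation
against cadaveric or clinical data is out of scope.
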