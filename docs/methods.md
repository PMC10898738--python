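# Methods

This note records the models implemented by `tenodesis-fe`, the defaults
and conventions chosen where the design was open, and what the synthetic
test inputs do and do not establish about real data.

## Surgical geometry

Bone tunnels are drilled by deleting every tetrahedron whose centroid lies
strictly inside the tunnel cylinder. This is deliberately not a CSG boolean
with remeshing: tunnel walls exist only to carry the `tunnel_wall` node set
used for graft fixation, so geometric fidelity of the wall is secondary and
the removed-volume accuracy is controlled by mesh resolution alone. With
~1 mm structured cells a 5 mm through-tunnel reproduces the analytic
cylinder volume to about 5 % (the suite enforces 15 %). Volume bookkeeping
is exact by construction: the input volume minus the output volume equals
the reported removed volume to machine precision.

Grafts are swept along planned trajectories with parallel-transport frames
(minimal rotation between consecutive segment tangents, which avoids frame
flipping on curved paths). Circular cross-sections use a 16-gon disk (one
hub plus ring nodes per station, three tetrahedra per wedge prism); the
polygonal area underestimates the circle by ~2.5 %, inside the 5 % analytic
check. Flat straps use one hexahedral cell per station pair split into six
tetrahedra; their volume is exact. A trajectory that turns tighter than the
cross-section half-size inverts swept cells and is rejected (the check is
on mixed signs of signed volumes before orientation normalization). The
iliotibial-band strap thickness is not a given quantity; it is
configuration with a 2 mm default.

Tibial compartment centers are placed at 25 % (medial) and 75 % (lateral)
of the plateau width measured **from the medial aspect**, along the line
joining the two aspects; this origin convention matches the medial/lateral
labeling order of the landmark pair. Femoral projections pick the mesh
vertex closest to the vertical line through a compartment center;
equidistant vertices resolve to the lowest index, deterministically.

All geometry is in millimetres, consistent with the mm–N–MPa unit system
of the exported decks.

## Constitutive models

Grafts use the uncoupled transversely isotropic Mooney–Rivlin solid with
the exponential-toe / linear fiber law (the formulation the target solver
ships for this material name): matrix coefficients c1, c2 (MPa), fiber toe
scale c3 (MPa) and rate c4, linear fiber modulus c5 (MPa), straightening
stretch λ* > 1, and the linear-branch offset c6 fixed by C0 continuity at
λ*. Curve fitting uses the incompressible uniaxial closed form, in which
the bulk modulus K drops out; K is therefore set separately for
near-incompressibility with default K = 1000·(c1 + c2) MPa.

Fitting is bounded nonlinear least squares (scipy trf) on
(c1, c2, c3, c4, c5, λ*) with residuals normalized by the peak stress and a
fixed, documented four-point multi-start (tight tolerances, best residual
wins), which makes the fit deterministic. On noise-free synthetic data of
40 points over λ ∈ [1, 1.10] all six parameters are recovered to well
under 2 %; with 2 % multiplicative noise and 200 points the linear fiber
modulus is recovered to ~1 %.

The posterior cruciate ligament abstraction is a bundle of tension-only
springs: zero force for non-positive displacement, piecewise-linear between
knots, and linear continuation of the final segment beyond the last knot —
extrapolation rather than a force cap, so large displacement steps do not
silently saturate.

Ligament in-situ strain is a fiber pre-stretch attached to a material
record. A stretch of exactly 1 is the reference state and produces a deck
identical to the no-prestrain deck; any other value is emitted as
per-element prestrain data for every domain bound to that material.

Fitted default parameter sets for the two graft tissues are synthetic
stand-ins on the stiffness scale of tendon (declared in
`assembly.SEMITENDINOSUS_LIKE` / `ITB_LIKE`); they are configuration, not
measurements.

## Loading protocols

The pivot-shift profile is parameterized as logistics because the published
curve is graphical only: f(θ) = 1/(1 + exp(−k(θ − 25°))) with k = ln 19/5
per degree, so the 5 %→95 % transition spans exactly 20°–30°. The
anterior–posterior femoral force is one continuous logistic from −25 N
(posterior) to +25 N rather than a discontinuous switch at 10°; the
posterior plateau holds below 10° within 1 %. Varus (7 N·m) and internal
(5 N·m) torques rise from zero through the same logistic; compression is a
constant 20 N. Sign convention: posterior force negative, anterior
positive.

Graft pretension direction: femoral orientations are sampled every 10°
over 0°–90° of flexion (from a solver forward run or the synthetic
generator — both produce the same `QuaternionSample` records); the
orientation at the fixation angle is obtained by SLERP between the
bracketing samples (quaternions canonicalized to non-negative scalar part,
shortest path enforced, near-parallel inputs fall back to normalized
lerp), converted to a rotation matrix, applied to the tunnel axis, and
scaled by the tension magnitude. The output norm equals the magnitude
exactly because the rotated direction is renormalized before scaling.

Step plans: native/injured knees run (1) prestrain, (2) pivot shift. The
reconstruction adds flexion to the 25° fixation angle, ramp pretension
plus node fixation, and return to full extension (taken as 0°, which is
not stated explicitly anywhere and is recorded here as a choice). The
combined surgery inserts the tenodesis flexion (to 30°) and fixation steps
immediately after the reconstruction fixation step, reflecting that the
tenodesis is performed after the reconstruction. Throughout, the tibia is
fixed in all six DoFs; during fixation steps the femur is fixed in
anterior–posterior and medial–lateral translation and internal–external
rotation with flexion prescribed, and it is free during the pivot shift.
Ramp curves are linear from 0 to peak over each step's unit pseudo-time.

The default pretension grid is 80 N ± 50 % in 10 N steps for the
reconstruction graft crossed with 5–60 N in 5 N steps for the tenodesis
graft (9 × 12 = 108 pairs). A finer 5 N reconstruction step (204 pairs) is
supported as an alternative configuration.

## Deck export and parsing

Decks are FEBio spec-3.0 XML: materials (including rigid bones with
center of mass), per-domain nodes/elements with 1-based contiguous ids,
node sets qualified as `domain::set`, surfaces and surface pairs,
sliding-elastic contact (penalty, tolerance, augmented Lagrangian flag and
search tolerance are configuration with placeholder defaults — the real
contact constants belong to a prior subject-specific model and are not
packaged), the three-cylindrical-joint chain between femur and tibia
(axes are configuration; phantom models define their own), load
controllers, and per-step rigid constraints, loads, and node-to-rigid
fixation constraints. A fixation registered at step *k* is emitted as
active in steps *k* onward and absent before, so its activation step
round-trips as the first step of appearance. Coordinates are printed with
17 significant digits; the parser inverts the writer to 1e-9, which the
randomized round-trip suite enforces. Unknown sections are preserved
opaquely with a warning. The package writes and reads decks; invoking a
solver is out of scope.

## Analysis conventions

Poses are the femur expressed in the tibia frame. ETR uses a
joint-coordinate-system style decomposition: intrinsic Euler sequence
Rx(α)Ry(β)Rz(γ) with the flexion axis x fixed in the femur and the long
axis z fixed in the tibia; ETR = −γ (external positive, equivalent to
negated internal femoral rotation). The test oracle is the independent
closed form γ = atan2(−R₀₁, R₀₀). PTT tracks the femur-projected lateral
compartment point through each pose and reports its posterior (−y)
displacement relative to the first output step; within-phase ranges are
offset-invariant, so the reference choice does not affect them.

MAE between differently sampled traces linearly resamples the candidate
onto the reference grid restricted to the overlap; disjoint coverage is an
error. Ranking ties break on lower reconstruction tension, then lower
tenodesis tension. The peri-tunnel stress radius defaults to 1.5× the
tunnel radius (configurable); the stress-reduction summary matches tables
at equal reconstruction tension, using the minimal-tenodesis row when
several share a tension, and reports deltas rounded to 2 decimals (errors
and stresses elsewhere report at 3 decimals). The summary's mean is the
mean of these matched deltas under that documented rule. Prestrain
calibration fits an ordinary least-squares line to the experimental
laxity points and selects the candidate stretch with minimal MSE against
the line, ties to the smaller stretch.

## Synthetic fixtures and what tests show

Phantom knees are boxes with the same labeling a segmented knee carries
(plateau aspects, tunnel cylinders, planned trajectories); they make every
pipeline operation executable and checkable, but they say nothing about
anatomical fidelity, cartilage contact, or insertion footprints. The
kinematics generator programs logistic ETR/PTT transitions rescaled to
span exactly the requested amplitudes over the sampled flexion range, so
closed-loop recovery is exact to 1e-6 without noise; with noise it is
statistical (3σ/√n plateau-mean bounds). Passing these suites establishes
that the computational pipeline is self-consistent — drilling conserves
volume, fitting recovers parameters, decks round-trip, metrics recover
programmed content — not that any specific clinical prediction is correct:
reproducing subject-specific kinematic curves would require real knee
geometry and a nonlinear FE solve, both outside this package.

The published pretension summary table is packaged verbatim as a fixture
(ten combined rows, nine standalone rows) so the ranking, comparison, and
stress-reduction operations are exercised against real study output.

Problem sizes in the default suites — 1 mm structured meshes of a
20×20×40 mm block (96 000 tetrahedra) for drilling, 40–200 point uniaxial
samples, 50 randomized decks, 1000 SLERP pairs — were chosen as the
smallest sizes at which the respective tolerances are meaningfully
exercised.

## Known limitations

* No viscoelasticity: graft tension relaxation over time is not modeled.
* No damage or failure criteria; stresses are reported, not interpreted.
* Uniaxial closed forms only in the materials module; full stress tensors
  come from the external solver.
* Contact parameter and cartilage/meniscus material defaults are
  placeholders flagged in configuration.
* The mesh-independence harness exposes its tolerance as configuration;
  no specific converged mesh is packaged.
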