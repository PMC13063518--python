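# Methods

`tmjmech` implements a desk-scale version of a patient-specific
temporomandibular joint (TMJ) biomechanics workflow: function-assessment
signal processing, a rigid-mandible forward-dynamics simulator with
muscle force tracking, articular-surface morphology metrics, and the
scaling-stress bookkeeping used to compare disc loading across subjects.
This note records the models, their assumptions, the parameters that
matter, and the design choices made where the design was genuinely open.

## Signal processing (module `signals`)

A unilateral clench task is recorded as a bite-force channel plus four
surface-EMG channels (left/right temporalis, left/right masseter) at
2000 Hz. Each EMG channel is detrended (full-series least-squares line),
full-wave rectified, low-pass filtered with a 4th-order Butterworth at
6 Hz, and normalized by the envelope's mean over an explicitly supplied
window covering the 20 N calibration bite. Filtering is applied
forward-backward (zero phase) so envelope timing stays aligned with the
force channel; the squared magnitude response is accounted for in the
tests' analytic expectations.

The ipsilateral-to-contralateral (IC) activation ratio of a muscle pair
is the ratio of the normalized envelopes' means over the task-bite
window. The mean (rather than peak or integral) is used as the most
robust single-scalar summary; both the statistic and the baseline
statistic are configuration points in principle, but only the defaults
are exposed.

The force channel is low-pass filtered the same way. Drift removal for
force is anchored to explicitly supplied rest (zero-force) windows: a
full-series linear detrend of a five-level staircase would shift its
absolute scale (a constant 50 N record would detrend to zero), which is
plainly not the intent of drift correction. When no rest windows are
supplied the force is used as-is. The task-bite segment is clipped and
linearly resampled onto 250 samples spanning exactly 0.25 s (inclusive
endpoints, so the window's final value — the reported final bite force —
is preserved exactly; the resulting sample rate is (n-1)/duration).

All analysis windows are explicit inputs, not auto-detected: plateau
detection is ill-posed on noisy records and would make the processing
non-deterministic.

## Constitutive laws (module `constitutive`)

* **Elastic foundation (EF) contact** for the articular cartilage
  layers: pressure p(d) = K ln(1 − d/h) with layer thickness
  h = 0.4 mm, elastic modulus E = 2.7 MPa, Poisson ratio ν = 0.49 and
  K = −(1−ν)E/((1+ν)(1−2ν)) = −46.208 MPa. p(0) = 0, and p diverges as
  the penetration approaches the layer thickness (bottoming out raises
  a saturation error rather than extrapolating).
* **Mooney–Rivlin** disc energy W = C1(I1−3) + C2(I2−3) with
  C1 = 0.9 MPa, C2 = 0.0009 MPa, and **Neo-Hookean** capsule energy
  W = C1(I1−3) with C1 = 1.44 MPa. Both are evaluated on isochoric
  deformations only (det F = 1 to 1e-6); no volumetric penalty term is
  invented, since the simulator transfers joint load through the EF
  model rather than a finite-element disc. The closed-form
  incompressible uniaxial Cauchy stress σ = 2(λ²−1/λ)(C1 + C2/λ) is
  provided as an independent oracle for the energy implementation.
* **Cable ligaments**: tension-only, force = k·max(0, (L−L0)/L0) with
  k = 250 N per unit strain and rest length L0 = initial length + slack
  length (slack lengths 4 / 1.9 / 1.9 / 7.5 / 4 / 0 / 0 mm for the
  anterior, medial, lateral, posterior, lateral temporomandibular,
  sphenomandibular and stylomandibular ligaments). Strain is referenced
  to the slack-inclusive rest length.
* **Hill-type static muscle**: clenching is quasi-static, so the
  force-velocity factor is unity and F = F_max(a·f_l(l̃) + f_p(l̃)) with
  l̃ = L/L_opt. Default curves: parabolic active curve of half-width
  0.5·l_opt peaking at 1, quadratic passive curve engaging beyond
  l_opt. The published model this emulates takes its Hill parameters
  from a reference model's supplement that is not reproduced here, so
  the curve shapes and strengths are package defaults and are
  overridable through the model configuration.

## Rigid-mandible simulator (module `simulator`)

The mandible is one rigid body (0.2 kg, diagonal inertia of order
3e-4 kg·m²) moving against a fixed cranium. Coordinates: +x
lateral-right, +y anterior, +z superior; files use mm-N-MPa-s, the
integrator works in SI internally.

**Planar bite constraint.** The tips of the left and right first
premolars and the lower incisor are held on the plane through their
rest positions (normal oriented superiorly). Holding three
non-collinear points on a plane removes the out-of-plane translation
and both out-of-plane rotations, leaving two in-plane translations and
the rotation about the plane normal free. The constraint is bilateral
and enforced with Lagrange multipliers at the velocity level plus an
exact position projection (residual < 1e-8 mm).

**Joint sites.** Each condyle is a sphere (radius 8 mm) inside a
cranium-fixed spherical socket (clearance 0.5 mm) carrying the EF law.
The contact force is the EF pressure integrated over the penetrating
spherical cap (24-point Gauss–Legendre in the polar angle; the
resultant is radial by symmetry). Because the penetration stiffness is
orders of magnitude above the other elements, the contact (and the
viscous damping) are treated implicitly in the velocity update —
the linearized contact stiffness enters the system matrix — making the
semi-implicit Euler step unconditionally stable at dt = 1 ms.

**Force tracking.** At each step the activations minimize

    1/2 w_c ||c̄ − H_c a||² + 1/2 w_a aᵀa + 1/2 w_d ||a_prev − a||²,
    0 ≤ a ≤ 1,

with weights w_c = 1, w_a = 0.0025, w_d = 1e-5. The tracking term is
squared (the standard strictly convex tracking QP; some descriptions
print an unsquared norm next to a squared damping term, which would not
be a QP). H_c is assembled by unit-activation perturbation: each
column is the normal bite force the muscle produces at the task-side
premolar with all other activations zero and the current passive state
subtracted, computed through the dynamically consistent
constraint-reaction projection λ = −(G M⁻¹ Gᵀ)⁻¹ G M⁻¹ w. The same
projection reports the achieved bite force, so tracking is exact up to
the (negligible) regularization bias whenever the target is reachable;
an unreachable target flags the result `saturated` instead of raising.
Measured IC ratios are imposed by merging each left/right temporalis
and masseter strand pair into one variable u with a_ipsi = r·u,
a_contra = u and bound u ≤ min(1, 1/r); the medial pterygoids keep
independent variables. The QP is solved exactly as a box-constrained
least-squares problem (BVLS) on the square-root-weighted stacked
system.

**Quasi-static character.** Viscous damping (150 N·s/m linear,
0.3 N·m·s/rad angular) settles the 0.25 s task to a true static
equilibrium: at the terminal step the residual of applied plus
constraint forces is below 1e-3 N and 1e-3 N·mm (typically ~1e-10).
The damping value is a compromise — strong enough to suppress contact-
mode ringing, weak enough that tangential creep converges within the
task; much heavier damping leaves a slowly creeping in-plane mode.

**What the constraint implies for joint loading.** With three landmark
points held on the plane, the out-of-plane force/moment balance is
carried entirely by the three constraint reactions; condylar load can
only develop through *in-plane* seating of the condyles against their
sockets. This is also the physical picture — the condyle loads the
eminence-like wall of the fossa, and the balancing-side condyle braces
laterally — but it means a purely vertical muscle transmits no load to
the joint under this constraint, and the textbook 2-D lever formula
does not literally apply. The simulator is therefore verified against
an independently derived closed-form static solution for this
architecture (anterior force balance against the EF socket solved by
bracketed root finding, out-of-plane reactions from the full 6-equation
balance), which it matches within 2%.

## Synthetic toy mandible (module `synthetic`)

`gen_toy_mandible` builds a bilaterally symmetric model sized to a
condyle-top-to-menton length of 117.8 mm by default: condyle tops at
(±30, 0, 0) mm, occlusal plane z = −40 through premolars (±14, 60, −40)
and incisor (0, 76, −40), menton on the midline with its anterior
coordinate solved so the length contract holds exactly. Six Hill-type
muscles per side (anterior/middle/posterior temporalis, superficial/
deep masseter, medial pterygoid) with strengths spanning 100–300 N and
anatomically ordered attachments (temporalis superior on the coronoid,
masseter lateral and oblique, medial pterygoid from a near-midline
origin to the medial angle); seven cable ligaments per side with the
slack lengths above; EF sphere-in-socket condyles pre-seated (just
touching) against a lateral + anterior-superior wall.

The geometry is deliberately tuned — by parametric simulation studies,
then frozen — so that the model exhibits the qualitative mechanics the
simulator is meant to demonstrate:

* every elevator has a uniform mild anterior obliquity, so clenching
  always seats the condyles and the joint-to-bite force ratio is a
  smooth function of geometry rather than a difference of cancelling
  terms;
* the condyles are wedged laterally, so a net medial force differential
  loads the *balancing-side* condyle; the strong near-midline medial
  pterygoid provides that differential during asymmetric tasks. This
  reproduces the clinically reported contralateral dominance of joint
  loading during unilateral biting, with both sides' loads inside the
  10–94% of-bite-force band reported across the modelling literature;
* the mandible length is anterior-posterior-dominated (narrow condyles,
  shallow menton), so rescaling raises the length faster than the
  resultant-muscle moment arm and the length/moment-arm ratio grows
  monotonically — giving the near-linear sweep relationship used as the
  force-tracking sanity check.

What the toy model does **not** emulate: real CBCT bone shapes, a
deformable disc (load transfer is the EF site model), occlusal anatomy,
neck or hyoid musculature, and any left-right asymmetry of anatomy.
Passing tests on this model therefore demonstrate correctness of the
mechanics and the processing chain, not clinical validity for any
patient.

The bite-recording generator produces five smooth ramp-hold bites at
the 10–50 N guided levels. Each EMG pair shares one band-limited
(20–450 Hz, the physiologic surface-EMG band) Gaussian carrier,
amplitude-modulated proportionally to force; per-channel relative
amplitude noise (default 5%) is added on top. The ipsilateral
modulation ramps from unity at the 20 N calibration bite to the
prescribed IC ratio at the task bite. This is a deliberate generator
design: the processing chain normalizes each channel by its own 20 N
baseline, so an imbalance present identically in every bite would
cancel; expressing it progressively makes the normalized-envelope ratio
over the task window equal the prescribed value, giving the chain a
recoverable ground truth.

## Surface morphology (module `surfaces`)

* **Joint gap**: per-vertex minimum Euclidean distance to the opposing
  triangulated surface, computed with exact point-to-triangle distances
  (vertex-to-vertex distance would bias high by the order of the edge
  length). Candidate triangles come from a KD-tree on triangle
  centroids with a nearest-vertex upper bound, which keeps the
  prefilter exact. At the 0.3 mm working mesh resolution the gap error
  against analytic fields is below the chordal sagitta (~1e-3 mm).
* **Principal curvatures**: per-vertex least-squares quadric fit (full
  second-order polynomial with linear terms) in the vertex tangent
  frame over the 2-ring neighborhood (configurable); the shape operator
  follows from the fundamental forms. Sign convention: convex with
  respect to the outward normal is positive, and outward means from
  bone into joint space on both surfaces — so a concave fossa facing a
  convex condyle carries negative curvatures and a perfectly congruent
  pair cancels. Vertices with fewer than six usable neighbors after one
  ring enlargement are flagged undefined (NaN) and excluded from
  summaries.
* **Congruency**: with D_i = k_min,i − k_max,i and
  A_i = (k_min,i + k_max,i)/2, the equivalent-surface principal
  curvatures are A_1 + A_2 ± sqrt(D_1² + D_2² − 2 D_1 D_2) and the
  congruency index is their root mean square; 0 marks perfectly matched
  surfaces. The radicand equals (D_1 − D_2)² and carries no dependence
  on the relative orientation of the two surfaces' principal
  directions; classical congruence formulations include a
  2 D_1 D_2 cos 2α cross-term, which is available behind the
  `relative_angle`/`orientation_aware` flag but is not the default.
  The per-point map anchors on the first surface, finds the closest
  point on the second (sharing the gap correspondence), and
  interpolates the partner curvatures barycentrically.

## Morphometrics and scaling stress (module `morphometrics`)

Landmark selections are averaged (three repetitions per landmark in the
measured data); intra-observer precision is summarized by the mean
radial error (mean Euclidean deviation of each selection from its set
centroid, pooled over sets). Biting arms are Euclidean distances from
first-premolar tips to condyle tops; condylar areas are the product of
the manually measured major and minor condylar axes (mesh-based axis
fitting is out of scope). The scaling stress is the unilateral final
bite force divided by the condylar area (N/mm² = MPa); it normalizes
disc stresses across subjects and pre/post-operative states. Raw values
are kept at full precision; printed-table rounding (half-up; 1 decimal
for morphometrics, 2 for scaling stress) is applied only at the
reporting layer. Differences between cases are computed at full
precision and then rounded.

## Mandible-length sweep (module `validation`)

The sanity check rescales the model's attachments, bite landmarks,
menton and center of mass along the anterior-posterior axis in
proportion to their distance from the condyle-top plane (condyles and
joint-site geometry preserved), simulates a 50 N left unilateral clench
with unit IC ratios at each length from 105 to 135 mm, and fits
normalized joint contact force (mean of the two joints' terminal
forces over bite force, per the bilateral-average convention) against
the ratio of mandible length to the resultant-muscle moment arm. Two
choices deserve note:

* the AP scale factor is solved (closed form / bracketed root) so the
  resulting 3-D condyle-to-menton length hits the target exactly; the
  naive length ratio would miss because the menton also has lateral and
  vertical offsets;
* ligament rest lengths and muscle optimal lengths are rescaled to the
  new attachment distances. A rescaled model represents a different
  subject with preserved relative geometry, not a pre-strained one;
  without this, stretched cables inject spurious passive bite force at
  the longer lengths.

The resultant moment arm is the perpendicular distance from the
inter-condylar axis to the line of action of the summed active-muscle
forces, anchored at the force-weighted centroid of the insertions and
evaluated at the terminal activations (rest pose; clench displacements
are below 0.1 mm). The sweep on the default toy model yields a strictly
increasing relationship with R² ≈ 0.99; the slope is geometry-specific.

## Numerical choices and degenerate inputs

* Tracking QP: BVLS with tol 1e-14; KKT residual of returned solutions
  ≲ 1e-8; solution invariant to muscle column ordering.
* Integration: dt = 1 ms (250 steps over the 0.25 s task, matching the
  resampled force curve); rotations via Rodrigues' formula with SVD
  re-orthonormalization; gyroscopic torque explicit.
* Linear fit: ordinary least squares; constant-y input reports R² as
  NaN (undefined) instead of dividing by zero; degenerate x raises.
* Gravity is included by default and toggleable; at 0.2 kg it shifts
  joint loads by well under one percentage point.
* Rounding for printed tables is decimal half-up, applied last.
* Simulations are deterministic: identical inputs produce bit-identical
  results; all synthetic generators are pure functions of their
  parameters and seed.

## Known limitations

* No finite-element disc or capsule: the constitutive laws are
  implemented and unit-verified, but joint load transfer uses the
  elastic-foundation site model, so intra-disc stress fields are out of
  scope.
* The planar bite constraint is bilateral; it can in principle pull on
  a landmark (negative bite pressure at the non-task points), which is
  an accepted idealization of the clench posture.
* Hill-type parameters are package defaults, not subject-calibrated.
* The congruency index, as defined, ignores principal-direction
  misalignment unless the orientation-aware variant is requested.
* Viscoelasticity, anisotropy and region-dependent disc properties are
  not modelled; mouth opening and chewing kinematics are out of scope.
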