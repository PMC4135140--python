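# Methods

This note documents the models, the numerical choices and the synthetic
study conditions behind otosim, in the spirit of a model-description
appendix: what is simulated, what the knobs mean, and what the passing
tests do and do not establish.

## Coordinate and unit conventions

Right-handed axes: X anterior–posterior, Y superior–inferior, Z
lateral–medial with +Z pointing medially (toward the inner ear, through the
footplate). All internal state is SI (m, kg, s, Pa, N); millimetres appear
only at I/O boundaries (configs, trajectory CSVs, report fields suffixed
`_mm`). Mesh volumes are returned in the cube of the mesh's coordinate
unit; voxel-grid volumes are reported in mm³.

## Synthetic anatomy

No patient geometry ships with the package; `geometry.build_scene` makes a
parametric stand-in whose few printed dimensions are anatomically anchored:

| element | default | note |
|---|---|---|
| footplate | 2.8 × 1.52 mm ellipse, 0.25 mm thick | elliptic plate, structured tet mesh |
| stapes superstructure | 0.6 × 0.6 × 1.2 mm block | fused to the footplate by stiff springs |
| incus | 0.5 × 0.5 × 2.6 mm block (the long process) | tip node named `incus_long_process_tip` |
| malleus | 0.6 × 0.6 × 1.5 mm block | embedded in the membrane at the umbo |
| tympanic membrane | r = 4 mm disc, 74 µm thick | rim fixed (tympanic annulus) |
| prosthesis | 0.4 mm × 4.5 mm piston, hexahedra | titanium: E = 344 MPa, ρ = 4500 kg/m³ |
| burr | Ø 0.6 mm sphere | |
| blocking rod | Ø 0.6 mm capsule | suction-cannula-like |
| speculum | Ø 6 mm aperture | visual-obstruction cone only |

Footplate thickness (0.25 mm), ossicle bone (E = 14.1 GPa,
ρ = 2200 kg/m³), membrane (E = 32 MPa), ligament/joint spring constants
(annular 100 N/m, joints 2000 N/m, membrane attachment 500 N/m) are
literature-typical middle-ear FEM values; every one is configurable and
tests are parameter-explicit. The incudomalleolar and incudostapedial
joints are isotropic spring attachments (three axis-aligned springs per
nearest-node pair): a joint capsule resists all relative motion, and a
gap-direction-only spring would leave near-free rigid modes on the stiff
ossicles.

Two deliberate departures from textbook element behaviour:

- The flat CST membrane has no bending stiffness, so its transverse
  response comes from a weak per-node tension foundation (50 N/m,
  `membrane_tension_stiffness`) standing in for the curvature/prestress of
  the real drum.
- The prosthesis hexahedra are assembled internally as a 6-tet split per
  cell, reusing the verified tetrahedral element.

## Mechanics

Linear elasticity, lumped mass, Rayleigh damping `C = αM + βK` with
α = 0 s⁻¹ and β = 10⁻⁴ s, Poisson 0.3 everywhere; implicit backward Euler
with Δt = 0.04 s solving `(M + ΔtC + Δt²K) Δv = Δt(f_ext + f_el − Cv −
ΔtKv) + p` by sparse LU (factor cached per Δt).

A corotational mode (per-tet polar decomposition, rotated forces against
the constant rest-state system matrix) is provided and verified to reduce
to the linear model as displacements vanish, but the **default is linear**:
with GPa bone and 0.04 s steps the explicit part of the constant-matrix
corotational correction is numerically unstable, and the simulated
procedures stay well inside the small-rotation regime (< 1° element
rotations), where the two models agree.

The harmonic (transfer-function) solver computes
`(K + iωC − ω²M)u = f` per frequency with the membrane pressure load and
reads the footplate-centre response; the static solver drops the inertial
and damping terms. The otosclerotic ("pathological") variant stiffens the
annular springs via `springs.annular_fixation_factor`.

## Drilling

Bone occupancy lives on a regular voxel grid of signed distances (0.02 mm
default spacing ≈ 30 voxels across the 0.6 mm burr). One carve update
applies `surface ← max(surface, −tool)` in the tool's padded bounding box
only; monotonicity, idempotence, locality and commutation of disjoint
carves follow and are asserted exactly in tests. Removed volume integrates
a clamped linear occupancy (material fraction `clip(½ − v/h, 0, 1)`);
binary voxel counting is kept as the brute-force oracle mode. Surfaces are
extracted with marching cubes (degenerate slivers welded). Tetrahedra whose
rest centroid ends up outside the material are deactivated (stiffness and
mass dropped; fully orphaned nodes frozen) — the minimal mechanically
consistent coupling of grid carving to the FEM. If an active drill's update
box is clipped by the grid while material sits on the touched face, the run
aborts with a domain error rather than silently losing bone.

The effective stapedotomy diameter is measured as the largest disc
inscribed (2-D Euclidean distance transform) in the set of voxel columns
drilled through the full plate thickness.

## Contact

Deformable-body nodes collide against tool signed-distance functions
(depth = margin − value, normal = normalized gradient; grid samples outside
the domain count as no contact). Edges and triangles are handled by point
sampling with deepest-sample deduplication. The unilateral problem is
solved on the backward-Euler velocity level: `λ ≥ 0`,
`Wλ + Jv_free − β·depth/Δt + Eλ ≥ 0`, complementarity — with
`W = J A⁻¹ Jᵀ` the Delassus operator, `β = 0.2` the per-step
penetration-correction fraction (full correction bounces on deep contacts),
and `E = diag(compliance)/Δt²` a per-contact regularization. Projected
Gauss–Seidel handles the generic case; because W is nearly rank-deficient
when many contacts share one stiff body, a direct active-set solve of the
equivalent convex QP polishes the iterate to the 1e-8 tolerance. Contacts
are frictionless.

Contact compliance is a modelling statement, not just regularization: the
crimp push reaches the incus through the thin titanium loop, so
grasper-side contacts carry the prosthesis compliance
(1/`prosthesis_contact_stiffness`, default 5 kN/m) while the steel rod and
burr are near-rigid (1 MN/m). Without this asymmetry a kinematic tool
squeezing the near-rigid incus against a rigid blocker has no feasible
solution.

The prosthesis is dragged by its grasp spring (50 N/m on the loop-end
nodes). The spring is kept inside the assembled stiffness and the moving
grasper enters as the equivalent anchor force `k(a(t) − a₀)` — the implicit
treatment; an explicit spring on the near-massless prosthesis diverges at
this time step. Snap-in is detected geometrically: engaged once the loop
centre clears the incus long-process axis by less than the detent threshold
(0.15 mm default), which is monotone along the push.

## Scripted procedures

Human teleoperation is replaced by scripted trajectories (timestamped
poses, linear/slerp interpolation, optional master-arm homothety 7:1
translation / 1:1 rotation, optional seeded band-limited tremor jitter of
5 µm RMS). "Execution time" is always simulated time.

- *Stapedotomy*: 4 s straight plunge through the footplate at the expert
  target; reports drilled volume, drilled fraction, hole diameter, minimum
  burr-to-target distance, visual-obstruction time.
- *Stapedioplasty*: 4 s script — approach from the parking pose (40 %),
  ramp the crimp push (40 %, default amplitude 0.25 mm, mostly +X with a
  small medial component, chosen to keep contact forces well under the
  0.9 N / 0.7 N damage thresholds), hold. The two-arm variant adds the
  blocking rod held still against the long process on the +X side with
  5 µm clearance. Reports the tip displacement trace, per-axis contact
  force on the incus, damage flags, engagement, and the complementarity
  residual.

The paired runs behind `scripts/acceptance.py` are a deliberately
scaled-down, operator-free twin of a robot user study: one synthetic scene,
one scripted push, 100 implicit steps per run (seconds of CPU). They test
the *mechanism* — a unilateral blocker cannot add displacement along the
axis it opposes, and here removes most of it — not inter-subject
variability, real anatomy, or absolute displacement magnitudes.

## What passing tests do not show

The synthetic blocks-and-springs anatomy reproduces scales and mechanisms,
not patient-specific responses: transfer-function magnitudes are not
calibrated against temporal-bone data; joints are linear springs without
physiological nonlinearity; contacts are frictionless; drilling removes
bone without heat, debris or fracture (superstructure removal is modelled
as total drilling); bleeding and visual rendering are out of scope. Results
should be read as comparisons between techniques on a fixed synthetic
scene, not as clinical predictions.
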