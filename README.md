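# otosim

A scriptable, testable simulator of middle-ear microsurgery. It reproduces
the two hardest gestures of otosclerosis surgery on a synthetic anatomy:

- **stapedotomy** — drilling a 0.6 mm hole through the stapes footplate with
  a spherical burr, and
- **stapedioplasty** — pushing a 0.4 mm × 4.5 mm piston prosthesis onto the
  incus long process until its loop snaps in (crimping), optionally while a
  second, blocking tool steadies the incus.

It is aimed at surgical-robotics researchers who want to compare tool
designs and two-handed techniques quantitatively — without a haptic device,
an operator, or patient imaging: tool motion comes from scripted,
timestamped trajectories, so every experiment is reproducible bit for bit.

## The model

**Anatomy (FEM).** The ossicular chain (malleus, incus, stapes) is built of
linear-elastic tetrahedra; the tympanic membrane is a disc of
constant-strain-triangle membrane elements; the annular ligament and the
ossicular joints are spring sets; the piston prosthesis is a hexahedral
body held by a generalized grasp spring. Mass is lumped, damping is Rayleigh
`C = αM + βK` with `α = 0 s⁻¹`, `β = 10⁻⁴ s`, Poisson's ratio 0.3, and time
integration is implicit backward Euler with `Δt = 0.04 s`.

**Bone drilling (SDF carving).** Bone is carried on a voxel grid of signed
distances (negative inside). One drill update is constructive-solid-geometry
subtraction, applied locally around the tool:

```
surface ← max(surface, −tool)
```

so material is only ever removed, the update is idempotent, and disjoint
carves commute. Surfaces are recovered by marching cubes; removed volume is
integrated with sub-voxel occupancy smoothing. Drilled-out tetrahedra are
deactivated in the mechanical model.

**Contact.** Tools collide with deformable bodies through their signed
distance functions; the unilateral problem (impulse λ ≥ 0, gap ≥ 0,
complementarity) is solved by projected Gauss–Seidel with an active-set
polish on the contact compliance operator.

**Procedure quality.** A run is scored by

```
E = α/S + β/F + γ/VF + δ · TF_after/TF_before ,   F = max_t |μ df/dt + λ ∫ f dt|
```

where `S` is the distance to the expert target, `f(t)` the force applied to
the anatomy, `VF` the time any tool obstructs the speculum viewing cone,
and the TF ratio compares the stapes transfer function (a virtual
audiometry) before and after the intervention.

## Worked example

Drill a centred stapedotomy on the default synthetic footplate
(2.8 × 1.52 mm ellipse, 0.25 mm thick) with the 0.6 mm burr:

```bash
otosim carve-demo --out-dir out --seed 1
```

prints

```
drilled 0.0705 mm^3 (8.43% of the footplate), hole diameter 0.600 mm
```

meaning: the scripted plunge removed 0.0705 mm³ of bone — 8.4 % of the
footplate, and almost exactly the analytic cylinder π·0.3²·0.25 = 0.0707 mm³
— leaving a through-hole whose largest inscribed disc matches the burr
diameter. `out/` receives the carved footplate surface (STL) and the full
report (JSON), including the burr path and the minimum distance to the
expert target.

The same from Python, plus a crimp comparison:

```python
from otosim import build_scene, fem, procedures

scene = build_scene()
traj  = procedures.make_crimp_trajectory(scene, seed=1)
rod   = procedures.make_blocking_trajectory(scene, traj)
one   = procedures.run_stapedioplasty(scene, traj, None, fem.SolverSettings(), seed=1)
two   = procedures.run_stapedioplasty(scene, traj, rod,  fem.SolverSettings(), seed=1)
print(procedures.displacement_reduction(one, two))   # {'total': 87.3, 'x': 94.7, ...}
```

The blocking rod held against the incus long process cuts the peak incus
excursion during crimping by ~87 % overall and ~95 % along the
anterior-posterior axis on this scene — the safety argument for two-armed
robotic crimping, since incus overload (≥ 0.9 N anterior-posterior or
0.7 N lateral-medial) risks luxation and total deafness.

Other entry points: `otosim build-scene` (export the synthetic meshes),
`otosim run stapedotomy|stapedioplasty --traj traj.csv [--second-arm rod.csv]`
(trajectory CSV columns `t,x,y,z,qw,qx,qy,qz,active,tool_id`, positions in
mm), `otosim evaluate --report report.json`.

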