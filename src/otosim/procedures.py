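"""Scripted procedure runner for the three middle-ear experiments:
stapedotomy (footplate drilling), single-arm stapedioplasty (prosthesis
crimping) and two-arm stapedioplasty (crimping with a blocking tool held
against the incus).

Human teleoperation is replaced by scripted tool trajectories, optionally
with seeded band-limited jitter as a tremor surrogate, so every run is
reproducible bit for bit.  "Execution time" in reports is simulated time
(the trajectory span), never wall clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation, Slerp

from . import collision, fem
from .carving import SDFGrid, carve, occupied_volume
from .evaluation import visual_obstruction_time
from .geometry import MM, RigidPose, Scene

__all__ = ["ToolTrajectory", "SafetyThresholds", "ProcedureReport",
           "TrajectoryDomainError", "run_stapedotomy", "run_stapedioplasty",
           "damage_check", "displacement_reduction",
           "make_plunge_trajectory", "make_crimp_trajectory",
           "make_blocking_trajectory"]


class TrajectoryDomainError(RuntimeError):
    """The drill reached the edge of the stored SDF domain."""


@dataclass
class ToolTrajectory:
    """Timestamped rigid poses for one tool.

    Positions in metres, quaternions w,x,y,z (unit), timestamps strictly
    increasing.  `active` marks when the tool effector (drill) is engaged.
    """

    times: np.ndarray          # (n,) s
    positions: np.ndarray      # (n, 3) m
    quaternions: np.ndarray    # (n, 4) w,x,y,z
    tool_id: str = "tool"
    active: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.quaternions = np.atleast_2d(np.asarray(self.quaternions, float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory timestamps must be strictly increasing")
        norms = np.linalg.norm(self.quaternions, axis=1)
        self.quaternions = self.quaternions / norms[:, None]
        if self.active is None:
            self.active = np.ones(len(self.times), bool)
        self.active = np.asarray(self.active, bool)

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def sample(self, t: float) -> tuple[RigidPose, bool]:
        """Linear position / slerp orientation interpolation; clamped."""
        t = float(np.clip(t, self.times[0], self.times[-1]))
        i = int(np.searchsorted(self.times, t, side="right") - 1)
        i = min(i, len(self.times) - 2) if len(self.times) > 1 else 0
        if len(self.times) == 1:
            return RigidPose(self.positions[0], self.quaternions[0]), \
                bool(self.active[0])
        t0, t1 = self.times[i], self.times[i + 1]
        a = (t - t0) / (t1 - t0)
        pos = (1 - a) * self.positions[i] + a * self.positions[i + 1]
        q = self.quaternions[[i, i + 1]][:, [1, 2, 3, 0]]  # -> x,y,z,w
        rot = Slerp([0.0, 1.0], Rotation.from_quat(q))(a)
        x, y, z, w = rot.as_quat()
        return RigidPose(pos, np.array([w, x, y, z])), bool(self.active[i])

    def apply_homothety(self, translation_scale: float = 7.0,
                        rotation_scale: float = 1.0) -> "ToolTrajectory":
        """Interpret master-arm motion as slave motion: translations about
        the first pose are divided by the homothetic translation scale
        (default 7); rotations are scaled by `rotation_scale` (default 1)."""
        p0 = self.positions[0]
        pos = p0 + (self.positions - p0) / translation_scale
        if rotation_scale == 1.0:
            quat = self.quaternions.copy()
        else:
            q0 = Rotation.from_quat(self.quaternions[0][[1, 2, 3, 0]])
            quat = np.empty_like(self.quaternions)
            for i, q in enumerate(self.quaternions):
                r = Rotation.from_quat(q[[1, 2, 3, 0]])
                rel = (q0.inv() * r).as_rotvec() * rotation_scale
                x, y, z, w = (q0 * Rotation.from_rotvec(rel)).as_quat()
                quat[i] = (w, x, y, z)
        return ToolTrajectory(self.times.copy(), pos, quat, self.tool_id,
                              self.active.copy())

    def with_jitter(self, amplitude: float, seed: int,
                    window: int = 5) -> "ToolTrajectory":
        """Seeded band-limited positional jitter (moving-average-filtered
        white noise, RMS `amplitude` metres) — a tremor surrogate."""
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(self.positions.shape)
        kern = np.ones(window) / window
        for c in range(3):
            noise[:, c] = np.convolve(noise[:, c], kern, mode="same")
        rms = np.sqrt(np.mean(noise ** 2))
        if rms > 0:
            noise *= amplitude / rms
        return ToolTrajectory(self.times.copy(), self.positions + noise,
                              self.quaternions.copy(), self.tool_id,
                              self.active.copy())

    def to_csv(self, path) -> None:
        """CSV columns t, x, y, z (mm), qw..qz, active, tool_id."""
        df = pd.DataFrame({
            "t": self.times,
            "x": self.positions[:, 0] / MM, "y": self.positions[:, 1] / MM,
            "z": self.positions[:, 2] / MM,
            "qw": self.quaternions[:, 0], "qx": self.quaternions[:, 1],
            "qy": self.quaternions[:, 2], "qz": self.quaternions[:, 3],
            "active": self.active.astype(int), "tool_id": self.tool_id,
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, tool_id: str | None = None) -> "ToolTrajectory":
        df = pd.read_csv(path)
        if tool_id is not None:
            df = df[df["tool_id"] == tool_id]
        tid = tool_id or (str(df["tool_id"].iloc[0])
                          if "tool_id" in df else "tool")
        active = (df["active"].to_numpy(bool) if "active" in df else None)
        return cls(df["t"].to_numpy(), df[["x", "y", "z"]].to_numpy() * MM,
                   df[["qw", "qx", "qy", "qz"]].to_numpy(), tid, active)


@dataclass
class SafetyThresholds:
    """Force limits beyond which severe ossicular damage is assumed:
    0.9 N anterior-posterior (X), 0.7 N lateral-medial (Z)."""

    anterior_posterior_limit: float = 0.9   # N, X axis
    lateral_medial_limit: float = 0.7       # N, Z axis

    def __post_init__(self) -> None:
        if self.anterior_posterior_limit <= 0 or self.lateral_medial_limit <= 0:
            raise ValueError("safety limits must be > 0")


def damage_check(force_trace: np.ndarray,
                 thr: SafetyThresholds | None = None) -> dict[str, bool]:
    """Per-axis damage flags: set when |F| exceeds the axis limit at any
    sample.  No limit is defined for the Y axis."""
    thr = thr or SafetyThresholds()
    tr = np.atleast_2d(np.asarray(force_trace, float))
    if not np.isfinite(tr).all():
        raise ValueError("force trace must be finite")
    return {
        "x": bool(tr.size and np.any(np.abs(tr[:, 0])
                                     > thr.anterior_posterior_limit)),
        "z": bool(tr.size and np.any(np.abs(tr[:, 2])
                                     > thr.lateral_medial_limit)),
    }


@dataclass
class ProcedureReport:
    """Per-procedure metrics (distances in mm, forces in N, times in s)."""

    procedure: str
    simulated_duration_s: float
    tool_path: dict = field(default_factory=dict)
    min_target_distance_mm: float | None = None
    drilled_volume_mm3: float = 0.0
    drilled_fraction_pct: float = 0.0
    hole_effective_diameter_mm: float = 0.0
    incus_displacement_trace_mm: list = field(default_factory=list)
    incus_peak_per_axis_mm: list = field(default_factory=lambda: [0.0] * 3)
    incus_peak_total_mm: float = 0.0
    force_trace_n: list = field(default_factory=list)
    damage_flags: dict = field(default_factory=dict)
    engaged: bool = False
    visual_obstruction_s: float = 0.0
    max_complementarity_residual: float = 0.0
    score_inputs: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.simulated_duration_s < 0:
            raise ValueError("duration must be >= 0")
        if self.drilled_volume_mm3 < 0:
            raise ValueError("drilled volume must be >= 0")


def _record_path(report: ProcedureReport, tool_id: str, t: float,
                 pose: RigidPose) -> None:
    entry = report.tool_path.setdefault(
        tool_id, {"t": [], "position_mm": [], "quaternion": []})
    entry["t"].append(float(t))
    entry["position_mm"].append([float(v) for v in pose.position / MM])
    entry["quaternion"].append([float(v) for v in pose.quaternion])


def _check_domain(sdf: SDFGrid, region, clipped: bool) -> None:
    """If the requested carve region was clipped by the grid and material
    sits on the touched domain face, updates are being lost."""
    if not clipped:
        return
    for ax in range(3):
        lo, hi = region[ax]
        for face, is_edge in ((lo, lo == 0), (hi, hi == sdf.dims[ax])):
            if not is_edge:
                continue
            sl = [slice(r[0], r[1]) for r in region]
            sl[ax] = slice(face if face < sdf.dims[ax] else face - 1,
                           (face + 1) if face < sdf.dims[ax] else face)
            if np.any(sdf.values[tuple(sl)] <= 0):
                raise TrajectoryDomainError(
                    "drill trajectory reaches the edge of the SDF domain; "
                    "enlarge sdf.padding")


def _through_hole_diameter(initial: SDFGrid, final: SDFGrid) -> float:
    """Effective diameter (mm) of the largest disc inscribed in the set of
    voxel columns drilled through the full plate thickness."""
    from scipy import ndimage

    mat0 = initial.values <= 0
    col_has = mat0.any(axis=2)
    removed_through = col_has & ~((final.values <= 0) & mat0).any(axis=2)
    if not removed_through.any():
        return 0.0
    edt = ndimage.distance_transform_edt(removed_through,
                                         sampling=final.spacing)
    return float(2.0 * edt.max() / MM)


def _step_times(traj: ToolTrajectory, dt: float) -> np.ndarray:
    n = max(1, int(round(traj.span / dt)))
    return traj.times[0] + dt * np.arange(1, n + 1)


def run_stapedotomy(scene: Scene, traj: ToolTrajectory,
                    settings: fem.SolverSettings | None = None,
                    seed: int | None = None,
                    update_scene: bool = True) -> ProcedureReport:
    """Drill the stapes footplate along a scripted burr trajectory.

    Steps the coupled FEM / carving / contact loop; tetrahedra whose centroid
    loses its material are deactivated (their stiffness and mass dropped).
    Reports drilled volume, drilled fraction of the footplate, minimum burr-
    centre distance to the expert target, and the effective through-hole
    diameter.
    """
    settings = settings or fem.SolverSettings()
    dt = settings.time_step
    burr, _ = scene.tools["burr"]
    sdf = scene.sdf_grids["footplate"].copy()
    sdf.carved_total_mm3 = 0.0
    initial = sdf.copy()
    initial_volume = occupied_volume(initial)

    deactivated = {"footplate": np.zeros(
        len(scene.bodies["footplate"].mesh.tetrahedra), bool)}
    sys = fem.assemble_system(scene)
    state = fem.MechState(sys.x0.copy(), np.zeros(sys.ndof), traj.times[0])
    centroids = scene.bodies["footplate"].mesh.nodes[
        scene.bodies["footplate"].mesh.tetrahedra].mean(axis=1)

    report = ProcedureReport("stapedotomy", traj.span, seed=seed)
    min_dist = np.inf
    max_resid = 0.0
    times = _step_times(traj, dt)
    fp_off = sys.node_offsets["footplate"]
    fp_n = sys.node_counts["footplate"]

    for t in times:
        pose, active = traj.sample(t)
        _record_path(report, traj.tool_id, t, pose)
        min_dist = min(min_dist,
                       np.linalg.norm(pose.position - scene.target_point))

        res = carve(sdf, burr, pose, active)
        r = burr.bounding_radius() + sdf.spacing
        lo = (pose.position - r - sdf.origin) / sdf.spacing
        hi = (pose.position + r - sdf.origin) / sdf.spacing
        clipped = bool(np.any(lo < 0) or np.any(hi > np.asarray(sdf.dims) - 1))
        _check_domain(sdf, res.region, clipped and active)

        if res.removed_mm3 > 0:
            mask = sdf.sample(centroids) > 0
            if np.any(mask != deactivated["footplate"]):
                deactivated["footplate"] = mask
                sys = fem.assemble_system(scene, deactivated=deactivated)

        pos3 = state.positions.reshape(-1, 3)
        fp_pts = pos3[fp_off:fp_off + fp_n]
        # only nodes still attached to undrilled material can collide
        tets = scene.bodies["footplate"].mesh.tetrahedra
        active_nodes = np.unique(tets[~deactivated["footplate"]])
        comp = 1.0 / scene.config.get("springs", {}).get(
            "rigid_contact_stiffness", 1.0e6)
        contacts = collision.sdf_point_contacts(
            fp_pts[active_nodes], collision.PosedToolSDF(burr, pose), 0.0,
            "footplate", active_nodes, traj.tool_id, compliance=comp)
        lam, p = collision.solve_contacts(sys, state, contacts, dt, settings)
        state = fem.backward_euler_step(state, sys, None, p, settings)
        max_resid = max(max_resid, collision.complementarity_residual(
            sys, state, contacts, lam, dt))

    report.drilled_volume_mm3 = sdf.carved_total_mm3
    report.drilled_fraction_pct = (100.0 * sdf.carved_total_mm3
                                   / initial_volume if initial_volume else 0.0)
    report.hole_effective_diameter_mm = _through_hole_diameter(initial, sdf)
    report.min_target_distance_mm = float(min_dist / MM)
    report.max_complementarity_residual = max_resid
    path = report.tool_path.get(traj.tool_id, {"t": [], "position_mm": []})
    report.visual_obstruction_s = visual_obstruction_time(
        np.asarray(path["t"]), np.asarray(path["position_mm"]) * MM,
        scene.target_point, scene.speculum_diameter)
    report.score_inputs = {"S_mm": report.min_target_distance_mm,
                           "VF_s": report.visual_obstruction_s}
    if update_scene:
        scene.sdf_grids["footplate"] = sdf
    return report


def run_stapedioplasty(scene: Scene, traj: ToolTrajectory,
                       second_arm: ToolTrajectory | None = None,
                       settings: fem.SolverSettings | None = None,
                       seed: int | None = None) -> ProcedureReport:
    """Place and crimp the piston prosthesis along a scripted grasper
    trajectory, optionally with a second (blocking) tool held against the
    incus long process.

    The prosthesis is grasped through the generalized spring; the incus
    collides with the prosthesis carried by the grasper and with the
    blocking rod.  Records the incus long-process-tip displacement trace,
    the per-axis contact force on the incus, damage flags against the
    0.9 N / 0.7 N thresholds and the snap-in engaged flag.
    """
    settings = settings or fem.SolverSettings()
    dt = settings.time_step
    grasper, _ = scene.tools["grasper"]
    rod, _ = scene.tools["rod"]

    # The grasp anchor springs stay in the assembled stiffness so the spring
    # is treated implicitly (a stiff spring on the near-massless prosthesis
    # would detonate an explicit treatment at dt = 0.04 s); advecting the
    # anchor with the grasper pose turns into an external force
    # k (anchor(t) - anchor(0)) on the grasped nodes.
    sys = fem.assemble_system(scene)
    state = fem.MechState(sys.x0.copy(), np.zeros(sys.ndof), traj.times[0])

    pose0 = scene.tools["grasper"][1]
    pros_nodes = scene.bodies["prosthesis"].mesh.nodes
    grasp_sel = np.where(np.isclose(pros_nodes[:, 2],
                                    pros_nodes[:, 2].max()))[0]
    spr_cfg = scene.config.get("springs", {})
    att = collision.GraspAttachment(
        "prosthesis", grasp_sel, pose0.inverse_transform(pros_nodes[grasp_sel]),
        spr_cfg.get("grasp_stiffness", 50.0), spr_cfg.get("grasp_damping", 0.5))
    rest_anchors = pros_nodes[grasp_sel].copy()

    inc_off = sys.node_offsets["incus"]
    inc_n = sys.node_counts["incus"]
    comp_pros = 1.0 / spr_cfg.get("prosthesis_contact_stiffness", 5.0e3)
    comp_rigid = 1.0 / spr_cfg.get("rigid_contact_stiffness", 1.0e6)
    tip_dofs = sys.dof_indices(*scene.named_nodes["incus_long_process_tip"])
    pr_off = sys.node_offsets["prosthesis"]
    pr_n = sys.node_counts["prosthesis"]

    report = ProcedureReport("stapedioplasty", traj.span, seed=seed)
    disp_trace, force_trace = [], []
    max_resid = 0.0
    engaged = False

    for t in _step_times(traj, dt):
        pose, _ = traj.sample(t)
        _record_path(report, traj.tool_id, t, pose)
        pos3 = state.positions.reshape(-1, 3)
        inc_pts = pos3[inc_off:inc_off + inc_n]

        contacts = collision.sdf_point_contacts(
            inc_pts, collision.PosedToolSDF(grasper, pose), 0.0, "incus",
            np.arange(inc_n), traj.tool_id, compliance=comp_pros)
        if second_arm is not None:
            rod_pose, _ = second_arm.sample(t)
            _record_path(report, second_arm.tool_id, t, rod_pose)
            contacts += collision.sdf_point_contacts(
                inc_pts, collision.PosedToolSDF(rod, rod_pose), 0.0, "incus",
                np.arange(inc_n), second_arm.tool_id, compliance=comp_rigid)

        f_grasp = np.zeros(sys.ndof)
        anchors_now = pose.transform(att.local_anchors)
        for row, node in enumerate(att.node_indices):
            dofs = sys.dof_indices("prosthesis", int(node))
            f_grasp[dofs] = att.stiffness * (anchors_now[row]
                                             - rest_anchors[row])
        lam, p = collision.solve_contacts(sys, state, contacts, dt, settings,
                                          external_forces=f_grasp)
        state = fem.backward_euler_step(state, sys, f_grasp, p, settings)
        max_resid = max(max_resid, collision.complementarity_residual(
            sys, state, contacts, lam, dt))

        disp_trace.append((state.positions[tip_dofs]
                           - sys.x0[tip_dofs]) / MM)
        f_inc = np.zeros(3)
        for c, l in zip(contacts, lam):
            f_inc += c.normal * l / dt       # force exerted on the incus
        force_trace.append(f_inc)

        pros_now = state.positions.reshape(-1, 3)[pr_off:pr_off + pr_n]
        engaged = engaged or collision.snap_in_state(
            pros_now, scene.bodies["incus"].mesh)

    disp = np.array(disp_trace) if disp_trace else np.zeros((0, 3))
    force = np.array(force_trace) if force_trace else np.zeros((0, 3))
    report.incus_displacement_trace_mm = disp.tolist()
    if len(disp):
        report.incus_peak_per_axis_mm = np.abs(disp).max(axis=0).tolist()
        report.incus_peak_total_mm = float(
            np.linalg.norm(disp, axis=1).max())
    report.force_trace_n = force.tolist()
    report.damage_flags = damage_check(force) if len(force) else {}
    report.engaged = engaged
    report.max_complementarity_residual = max_resid
    all_paths = {k: np.asarray(v["position_mm"]) * MM
                 for k, v in report.tool_path.items()}
    t_path = np.asarray(report.tool_path[traj.tool_id]["t"])
    report.visual_obstruction_s = visual_obstruction_time(
        t_path, all_paths, scene.target_point, scene.speculum_diameter)
    report.score_inputs = {"VF_s": report.visual_obstruction_s}
    return report


def displacement_reduction(single: ProcedureReport,
                           dual: ProcedureReport) -> dict[str, float | None]:
    """Percent reduction of peak incus displacement from the single-tool to
    the two-tool run: 100 (single - dual) / single, per axis and total.
    Undefined (None) where the single-tool peak is zero."""
    out: dict[str, float | None] = {}
    pairs = {"total": (single.incus_peak_total_mm, dual.incus_peak_total_mm)}
    for ax, name in enumerate("xyz"):
        pairs[name] = (single.incus_peak_per_axis_mm[ax],
                       dual.incus_peak_per_axis_mm[ax])
    for key, (s, d) in pairs.items():
        out[key] = None if s == 0 else float(100.0 * (s - d) / s)
    return out


# ---------------------------------------------------------------------------
# scripted trajectories
# ---------------------------------------------------------------------------

def make_plunge_trajectory(scene: Scene, duration: float = 4.0,
                           standoff: float = 0.8e-3,
                           overshoot: float = 0.35e-3,
                           dt: float = 0.04) -> ToolTrajectory:
    """Straight drill plunge through the footplate at the expert target,
    entering from the lateral side and passing fully through the plate."""
    target = scene.target_point
    start = target + np.array([0.0, 0.0, -standoff])
    t_fp = scene.config["geometry"]["footplate"]["thickness"] * MM
    end = target + np.array([0.0, 0.0, t_fp + overshoot])
    n = max(2, int(round(duration / dt)) + 1)
    ts = np.linspace(0.0, duration, n)
    a = (ts / duration)[:, None]
    pos = (1 - a) * start + a * end
    quat = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
    return ToolTrajectory(ts, pos, quat, "burr")


def make_crimp_trajectory(scene: Scene, push_amplitude: float = 0.25e-3,
                          duration: float = 4.0, dt: float = 0.04,
                          seed: int | None = None,
                          jitter: float = 5e-6) -> ToolTrajectory:
    """Scripted crimp push: the grasper (carrying the prosthesis loop)
    advances against the incus long process, mostly anterior-posterior (+X)
    with a small medial (+Z) component, holds, and withdraws.

    The amplitude default keeps contact forces well below the 0.9 / 0.7 N
    damage thresholds; `seed` adds band-limited tremor jitter.
    """
    inc = scene.config["geometry"]["incus"]
    tip = np.array([inc["center"][0], inc["center"][1],
                    inc["center"][2] + inc["size"][2] / 2]) * MM
    face_x = tip[0] - inc["size"][0] / 2 * MM
    clearance = 0.05e-3
    # back-wall inner face sits at the grasper origin's local x = 0
    start = np.array([face_x - clearance, tip[1], tip[2]])
    push_dir = np.array([1.0, 0.0, 0.15])
    push_dir /= np.linalg.norm(push_dir)
    home = scene.tools["grasper"][1].position

    n = max(4, int(round(duration / dt)) + 1)
    ts = np.linspace(0.0, duration, n)
    # approach from the scene grasper pose over 40% of the script, ramp the
    # crimp push over the next 40%, then hold
    a = np.clip(ts / (0.4 * duration), 0.0, 1.0)[:, None]
    pos = (1 - a) * home + a * start
    prog = np.clip((ts - 0.4 * duration) / (0.4 * duration), 0.0, 1.0)
    pos = pos + np.outer(prog * push_amplitude, push_dir)
    quat = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
    traj = ToolTrajectory(ts, pos, quat, "grasper")
    if seed is not None and jitter > 0:
        traj = traj.with_jitter(jitter, seed)
    return traj


def make_blocking_trajectory(scene: Scene, traj: ToolTrajectory,
                             clearance: float = 5e-6) -> ToolTrajectory:
    """Blocking rod held still against the incus long process on the side
    opposite the prosthesis approach (+X side), axis pointing back out of
    the speculum (world -Z)."""
    inc = scene.config["geometry"]["incus"]
    rod = scene.tools["rod"][0].dims
    tip = np.array([inc["center"][0], inc["center"][1],
                    inc["center"][2] + inc["size"][2] / 2]) * MM
    x = tip[0] + inc["size"][0] / 2 * MM + rod["diameter"] / 2 + clearance
    pos = np.array([x, tip[1], tip[2] + 0.2e-3])
    # rotate local +Z (rod axis) onto world -Z
    quat = np.array([0.0, 1.0, 0.0, 0.0])
    ts = np.array([traj.times[0], traj.times[-1]])
    return ToolTrajectory(ts, np.tile(pos, (2, 1)), np.tile(quat, (2, 1)),
                          "rod")
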