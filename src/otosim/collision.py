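"""Tool/tissue contact: detection against signed-distance fields, unilateral
resolution by projected Gauss-Seidel on the contact compliance (Delassus)
operator, the generalized grasp spring, and the prosthesis snap-in detector.

Contacts are frictionless by default (a Coulomb model is out of scope here):
each contact enforces a nonnegative normal impulse, a nonnegative post-step
normal gap, and complementarity between the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .carving import SDFGrid
from .fem import MechState, SolverSettings, SystemMatrices
from .geometry import RigidPose, TetMesh, ToolShape

logger = logging.getLogger(__name__)

__all__ = ["Contact", "GraspAttachment", "PosedToolSDF", "sdf_point_contacts",
           "sample_feature_contacts", "solve_contacts", "grasp_spring_force",
           "snap_in_state"]


@dataclass
class Contact:
    """One unilateral contact record."""

    point: np.ndarray          # (3,) m
    normal: np.ndarray         # unit, direction that separates the bodies
    depth: float               # m, >= 0 when touching/penetrating
    body_id: str
    feature_id: int            # node index on the body
    tool_id: str = ""
    compliance: float = 0.0    # m/N; > 0 for a compliant (springy) contact

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, float)
        n = np.linalg.norm(self.normal)
        if not np.isclose(n, 1.0, atol=1e-6):
            self.normal = self.normal / n
        if self.depth < 0:
            raise ValueError("emitted contacts must have depth >= 0")


class PosedToolSDF:
    """Adapter exposing a rigid tool at a pose as a world-frame SDF with
    value/normal queries (same interface as SDFGrid)."""

    def __init__(self, tool: ToolShape, pose: RigidPose):
        self.tool = tool
        self.pose = pose

    def sample(self, pts: np.ndarray) -> np.ndarray:
        return self.tool.sdf(pts, self.pose)

    def gradient(self, pts: np.ndarray, h: float = 1e-6) -> np.ndarray:
        pts = np.atleast_2d(pts)
        grad = np.zeros_like(pts)
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = h
            grad[:, ax] = (self.sample(pts + e) - self.sample(pts - e)) / (2 * h)
        return grad


def sdf_point_contacts(points: np.ndarray, sdf: SDFGrid | PosedToolSDF,
                       margin: float = 0.0, body_id: str = "",
                       node_indices: np.ndarray | None = None,
                       tool_id: str = "", compliance: float = 0.0
                       ) -> list[Contact]:
    """Contacts for every point whose signed distance is below `margin`.

    depth = margin - value; normal = normalized SDF gradient at the point.
    Points outside a grid's domain sample +inf and therefore never contact.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    points = np.atleast_2d(points)
    node_indices = (np.arange(len(points)) if node_indices is None
                    else np.asarray(node_indices, int))
    vals = sdf.sample(points)
    hit = np.where(vals < margin)[0]
    if hit.size == 0:
        return []
    normals = sdf.gradient(points[hit])
    contacts = []
    for row, i in enumerate(hit):
        n = normals[row]
        norm = np.linalg.norm(n)
        if norm < 1e-12 or not np.isfinite(norm):
            continue  # degenerate gradient (e.g. medial axis)
        contacts.append(Contact(points[i].copy(), n / norm,
                                float(margin - vals[i]), body_id,
                                int(node_indices[i]), tool_id, compliance))
    return contacts


def sample_feature_contacts(feature: np.ndarray, sdf, samples: int,
                            margin: float = 0.0, body_id: str = "",
                            feature_id: int = 0,
                            tool_id: str = "") -> list[Contact]:
    """Contact for an edge (2x3) or triangle (3x3) feature, by sampling it
    with points and keeping the deepest penetrating sample."""
    feature = np.asarray(feature, float)
    if feature.shape[0] == 2:
        if samples < 2:
            raise ValueError("edges need >= 2 samples")
        t = np.linspace(0.0, 1.0, samples)[:, None]
        pts = (1 - t) * feature[0] + t * feature[1]
    elif feature.shape[0] == 3:
        if samples < 3:
            raise ValueError("triangles need >= 3 samples")
        n = max(2, int(np.ceil((np.sqrt(8 * samples + 1) - 1) / 2)))
        bary = [(i / n, j / n) for i in range(n + 1)
                for j in range(n + 1 - i)]
        bc = np.array([(1 - a - b, a, b) for a, b in bary])
        pts = bc @ feature
    else:
        raise ValueError("feature must be an edge (2x3) or triangle (3x3)")
    cs = sdf_point_contacts(pts, sdf, margin, body_id, tool_id=tool_id)
    if not cs:
        return []
    deepest = max(cs, key=lambda c: c.depth)
    deepest.feature_id = feature_id
    return [deepest]


def _contact_jacobian(sys: SystemMatrices, contacts: list[Contact]
                      ) -> np.ndarray:
    """Rows map free nodal velocities to normal relative velocities."""
    J = np.zeros((len(contacts), sys.ndof))
    for r, c in enumerate(contacts):
        dofs = sys.dof_indices(c.body_id, c.feature_id)
        J[r, dofs] = c.normal
    J[:, ~sys.free] = 0.0
    return J


def solve_contacts(sys: SystemMatrices, state: MechState,
                   contacts: list[Contact], dt: float,
                   settings: SolverSettings | None = None,
                   external_forces: np.ndarray | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Unilateral contact impulses by projected Gauss-Seidel.

    Solves, on the backward-Euler velocity level, for impulses lambda >= 0
    such that the post-step normal velocity removes the current penetration
    (v_n >= depth/dt), with complementarity lambda * residual = 0.  Returns
    (lambda per contact, nodal impulse vector J^T lambda).
    """
    settings = settings or SolverSettings()
    p = np.zeros(sys.ndof)
    lam = np.zeros(len(contacts))
    if not contacts:
        return lam, p

    f_ext = (np.zeros(sys.ndof) if external_forces is None
             else np.asarray(external_forces, float))
    f_el = sys.elastic_force(state.positions, settings.corotational)
    rhs = dt * (f_ext + f_el - sys.C @ state.velocities
                - dt * (sys.K @ state.velocities))
    v_free = state.velocities + sys.solve(dt, rhs)
    v_free[~sys.free] = 0.0

    J = _contact_jacobian(sys, contacts)
    # Delassus operator W = J A^-1 J^T, regularized by per-contact
    # compliance (an implicit contact spring of stiffness 1/compliance)
    AinvJt = np.stack([sys.solve(dt, J[r]) for r in range(len(contacts))],
                      axis=1)
    W = J @ AinvJt
    E = np.array([c.compliance for c in contacts]) / (dt * dt)
    W = W + np.diag(E)
    depths = np.array([c.depth for c in contacts])
    erp = getattr(settings, "contact_erp", 1.0)
    b = J @ v_free - erp * depths / dt

    diag = np.diag(W).copy()
    diag[diag <= 0] = 1.0
    scale = max(1.0, float(np.abs(b).max()))
    tol = settings.contact_tolerance * scale

    def kkt_ok(l):
        res = b + W @ l
        return (float(np.maximum(-res, 0.0).max(initial=0.0)) < tol
                and float(np.abs(l * res).max(initial=0.0)) < tol)

    converged = False
    for _ in range(settings.contact_iterations):
        for i in range(len(contacts)):
            res = b[i] + W[i] @ lam
            lam[i] = max(0.0, lam[i] - res / diag[i])
        if kkt_ok(lam):
            converged = True
            break

    if not converged:
        # Gauss-Seidel stalls when W is nearly rank-deficient (a stiff body
        # shared by many contacts); polish with an active-set solve of the
        # equivalent convex QP, exact for these small frictionless systems.
        active = lam > 0
        for _ in range(4 * len(contacts) + 8):
            l_try = np.zeros_like(lam)
            if active.any():
                sub = np.ix_(active, active)
                l_try[active] = np.linalg.lstsq(W[sub], -b[active],
                                                rcond=None)[0]
            if l_try.min(initial=0.0) < -tol:
                active[np.argmin(l_try)] = False
                continue
            l_try = np.maximum(l_try, 0.0)
            res = b + W @ l_try
            worst = np.argmin(res)
            if res[worst] < -tol and not active[worst]:
                active[worst] = True
                continue
            lam = l_try
            converged = kkt_ok(lam)
            break
    if not converged:
        logger.warning("contact solver did not fully converge "
                       "(%d contacts); returning best iterate",
                       len(contacts))
    return lam, J.T @ lam


def complementarity_residual(sys: SystemMatrices, state_after: MechState,
                             contacts: list[Contact], lam: np.ndarray,
                             dt: float) -> float:
    """max_i lambda_i * max(residual_i, 0) over contacts, where residual is
    the violated part of the velocity-level constraint."""
    if not contacts:
        return 0.0
    J = _contact_jacobian(sys, contacts)
    depths = np.array([c.depth for c in contacts])
    E = np.array([c.compliance for c in contacts]) / (dt * dt)
    erp = 0.2
    g = J @ state_after.velocities - erp * depths / dt + E * lam
    return float(np.max(lam * np.maximum(-g, 0.0)))


@dataclass
class GraspAttachment:
    """Generalized spring tying prosthesis nodes to the grasper pose."""

    body_id: str
    node_indices: np.ndarray
    local_anchors: np.ndarray     # (n, 3) anchor points in the tool frame
    stiffness: float              # N/m
    damping: float = 0.0          # N*s/m

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError("grasp stiffness must be > 0")
        self.node_indices = np.asarray(self.node_indices, int)
        self.local_anchors = np.atleast_2d(np.asarray(self.local_anchors,
                                                      float))


def grasp_spring_force(att: GraspAttachment, pose: RigidPose,
                       state: MechState, sys: SystemMatrices) -> np.ndarray:
    """Nodal forces of the generalized grasp spring:
    f = -k (x - anchor(pose)) - c (v - anchor velocity), anchors advected
    rigidly by the tool pose (anchor velocity taken as zero per step)."""
    f = np.zeros(sys.ndof)
    anchors = pose.transform(att.local_anchors)
    for row, node in enumerate(att.node_indices):
        dofs = sys.dof_indices(att.body_id, int(node))
        x = state.positions[dofs]
        v = state.velocities[dofs]
        f[dofs] += -att.stiffness * (x - anchors[row]) - att.damping * v
    return f


def snap_in_state(prosthesis_nodes: np.ndarray, incus_mesh: TetMesh,
                  params: dict | None = None) -> bool:
    """Geometric snap-in detector: True once the incus long process lies
    inside the prosthesis loop aperture beyond the detent.

    The loop aperture centre is the centroid of the prosthesis grasp-end
    layer; the process centreline is the incus principal axis.  Engagement =
    centreline clearance below `engage_threshold` (default 0.15 mm), which is
    monotone along the push approach.
    """
    params = params or {}
    thr = params.get("engage_threshold", 0.15e-3)
    nodes = np.atleast_2d(np.asarray(prosthesis_nodes, float))
    zmax = nodes[:, 2].max()
    loop_center = nodes[nodes[:, 2] >= zmax - 1e-4].mean(axis=0)

    inc = incus_mesh.nodes
    centroid = inc.mean(axis=0)
    cov = np.cov((inc - centroid).T)
    axis = np.linalg.eigh(cov)[1][:, -1]   # principal (long) axis
    half = np.abs((inc - centroid) @ axis).max()
    t = np.clip((loop_center - centroid) @ axis, -half, half)
    closest = centroid + t * axis
    return bool(np.linalg.norm(loop_center - closest) < thr)
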