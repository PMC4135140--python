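"""Small-deformation finite-element dynamics for the middle-ear scene.

Ossicles are linear-elastic tetrahedra (optionally with a corotational
per-element rotation for large displacements), the tympanic membrane is a
constant-strain-triangle membrane, ligaments/joints are linear springs, and
the prosthesis hexahedra are assembled from an internal 6-tet split of each
cell.  Mass is lumped (diagonal), damping is Rayleigh C = alpha*M + beta*K,
and time integration is implicit backward Euler, which is unconditionally
stable and mildly dissipative — the standard choice for interactive surgical
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import HexMesh, Scene, TetMesh, TriShell

__all__ = ["FemError", "SolverSettings", "MechState", "SystemMatrices",
           "tet_element_stiffness", "cst_membrane_stiffness",
           "rayleigh_damping", "assemble_system", "backward_euler_step",
           "harmonic_response", "static_solve"]


class FemError(RuntimeError):
    pass


@dataclass
class SolverSettings:
    """Integrator and contact-solver settings (defaults: 0.04 s implicit
    steps, corotational ossicles)."""

    time_step: float = 0.04            # s
    linear_tolerance: float = 1e-10
    corotational: bool = False
    contact_iterations: int = 400
    contact_tolerance: float = 1e-8
    # fraction of the penetration depth corrected per step; 1.0 removes it
    # in one step but can inject velocity (bounce) on deep contacts
    contact_erp: float = 0.2

    def __post_init__(self) -> None:
        if self.time_step <= 0:
            raise ValueError("time_step must be > 0")
        if self.linear_tolerance <= 0 or self.contact_tolerance <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class MechState:
    """Nodal kinematic state: flat arrays of length 3*n_nodes."""

    positions: np.ndarray
    velocities: np.ndarray
    time: float = 0.0

    def copy(self) -> "MechState":
        return MechState(self.positions.copy(), self.velocities.copy(),
                         self.time)


# ---------------------------------------------------------------------------
# element matrices
# ---------------------------------------------------------------------------

def _isotropic_D(young: float, poisson: float) -> np.ndarray:
    lam = young * poisson / ((1 + poisson) * (1 - 2 * poisson))
    mu = young / (2 * (1 + poisson))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = np.eye(3) * mu
    return D


def tet_element_stiffness(coords: np.ndarray, young: float,
                          poisson: float) -> np.ndarray:
    """12x12 stiffness of a linear (constant-strain) tetrahedron.

    Voigt order (xx, yy, zz, xy, yz, zx) with engineering shear strains.
    Raises FemError for degenerate or inverted elements.
    """
    coords = np.asarray(coords, float)
    Dm = (coords[1:] - coords[0]).T          # columns p1-p0, p2-p0, p3-p0
    vol = np.linalg.det(Dm) / 6.0
    if vol <= 0:
        raise FemError("degenerate or inverted tetrahedron")
    grads = np.zeros((4, 3))
    grads[1:] = np.linalg.inv(Dm)            # rows: grad of barycentric coords
    grads[0] = -grads[1:].sum(axis=0)
    B = np.zeros((6, 12))
    for i in range(4):
        gx, gy, gz = grads[i]
        c = 3 * i
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c], B[3, c + 1] = gy, gx
        B[4, c + 1], B[4, c + 2] = gz, gy
        B[5, c], B[5, c + 2] = gz, gx
    D = _isotropic_D(young, poisson)
    return vol * B.T @ D @ B


def cst_membrane_stiffness(coords: np.ndarray, young: float, poisson: float,
                           thickness: float) -> np.ndarray:
    """9x9 stiffness of a constant-strain-triangle membrane element
    (in-plane plane-stress law scaled by thickness; no bending)."""
    coords = np.asarray(coords, float)
    e1 = coords[1] - coords[0]
    n = np.cross(e1, coords[2] - coords[0])
    area2 = np.linalg.norm(n)
    if area2 < 1e-300:
        raise FemError("zero-area membrane triangle")
    e1 = e1 / np.linalg.norm(e1)
    nrm = n / area2
    e2 = np.cross(nrm, e1)
    # local 2-D coordinates
    xy = np.stack([(coords - coords[0]) @ e1, (coords - coords[0]) @ e2],
                  axis=1)
    area = area2 / 2.0
    x, y = xy[:, 0], xy[:, 1]
    b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]])
    c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]])
    B = np.zeros((3, 6))
    for i in range(3):
        B[0, 2 * i] = b[i]
        B[1, 2 * i + 1] = c[i]
        B[2, 2 * i] = c[i]
        B[2, 2 * i + 1] = b[i]
    B /= 2.0 * area
    D = young / (1 - poisson ** 2) * np.array(
        [[1, poisson, 0], [poisson, 1, 0], [0, 0, (1 - poisson) / 2]])
    K6 = thickness * area * B.T @ D @ B
    P = np.zeros((9, 6))
    for i in range(3):
        P[3 * i:3 * i + 3, 2 * i] = e1
        P[3 * i:3 * i + 3, 2 * i + 1] = e2
    return P @ K6 @ P.T


def rayleigh_damping(M, K, alpha: float, beta: float):
    """C = alpha*M + beta*K (M may be a diagonal vector or a matrix)."""
    M = sp.diags(M) if np.ndim(M) == 1 else M
    if M.shape != K.shape:
        raise ValueError("M and K shape mismatch")
    return (alpha * M + beta * K).tocsr()


# hex cell -> 6 tets (corner v = 4i + 2j + k over cell-offset bits)
_VTK_TO_BITS = [0, 4, 6, 2, 1, 5, 7, 3]
_CUBE_TETS = [(0, 1, 3, 7), (0, 3, 2, 7), (0, 2, 6, 7),
              (0, 6, 4, 7), (0, 4, 5, 7), (0, 5, 1, 7)]


def _hex_to_tets(hex_nodes: np.ndarray) -> list[list[int]]:
    bits = [hex_nodes[_VTK_TO_BITS.index(b)] for b in range(8)]
    return [[bits[t[0]], bits[t[1]], bits[t[2]], bits[t[3]]]
            for t in _CUBE_TETS]


@dataclass
class SystemMatrices:
    """Assembled global system: lumped mass (diagonal), stiffness, Rayleigh
    damping, free-dof mask, and per-element data for corotational forces."""

    M: np.ndarray                    # (ndof,) lumped diagonal
    K: sp.csr_matrix
    C: sp.csr_matrix
    free: np.ndarray                 # (ndof,) bool
    x0: np.ndarray                   # rest positions, flat
    node_offsets: dict[str, int]     # body -> first global node index
    node_counts: dict[str, int]
    corotational_elements: list = field(default_factory=list)
    _factors: dict = field(default_factory=dict, repr=False)

    @property
    def ndof(self) -> int:
        return self.M.size

    def dof_indices(self, body: str, node: int) -> np.ndarray:
        g = self.node_offsets[body] + node
        return np.arange(3 * g, 3 * g + 3)

    def system_matrix(self, dt: float) -> sp.csr_matrix:
        return (sp.diags(self.M) + dt * self.C + dt * dt * self.K).tocsr()

    def factorized(self, dt: float):
        key = round(dt, 12)
        if key not in self._factors:
            A = self.system_matrix(dt)[np.ix_(self.free, self.free)].tocsc()
            try:
                self._factors[key] = spla.splu(A)
            except RuntimeError as exc:  # pragma: no cover - defensive
                raise FemError(
                    "singular dynamic system; fix or ground every body "
                    f"({exc})") from exc
        return self._factors[key]

    def solve(self, dt: float, rhs_full: np.ndarray) -> np.ndarray:
        out = np.zeros(self.ndof)
        out[self.free] = self.factorized(dt).solve(rhs_full[self.free])
        return out

    def elastic_force(self, positions: np.ndarray,
                      corotational: bool = False) -> np.ndarray:
        """Internal elastic force at the given nodal positions.

        Linear: -K (x - x0).  Corotational: tetrahedra evaluate
        -R Ke (R^T x - x0) with R from the polar decomposition of the
        element deformation gradient; membrane/springs stay linear.
        """
        u = positions - self.x0
        if not corotational or not self.corotational_elements:
            return -self.K @ u
        f = -(self.K @ u)
        for dofs, Ke, Dm_inv, x0e in self.corotational_elements:
            xe = positions[dofs].reshape(4, 3)
            F = (xe[1:] - xe[0]).T @ Dm_inv
            U, _, Vt = np.linalg.svd(F)
            R = U @ Vt
            if np.linalg.det(R) < 0:
                U[:, -1] *= -1
                R = U @ Vt
            R12 = np.kron(np.eye(4), R)
            f_lin = -(Ke @ (positions[dofs] - x0e))
            f_cor = -(R12 @ (Ke @ (R12.T @ positions[dofs] - x0e)))
            f[dofs] += f_cor - f_lin
        return f


def assemble_system(scene: Scene, exclude_spring_tags: tuple[str, ...] = (),
                    deactivated: dict[str, np.ndarray] | None = None
                    ) -> SystemMatrices:
    """Assemble lumped mass, global stiffness (tets + membrane + springs) and
    Rayleigh damping for a scene; fixed dofs are masked out.

    `deactivated` maps a body name to a boolean per-element mask of elements
    whose material has been drilled away (their stiffness and mass are
    dropped).
    """
    deactivated = deactivated or {}
    offsets, counts = {}, {}
    n_nodes = 0
    for name, body in scene.bodies.items():
        offsets[name] = n_nodes
        counts[name] = len(body.mesh.nodes)
        n_nodes += counts[name]
    ndof = 3 * n_nodes

    x0 = np.concatenate([b.mesh.nodes.ravel() for b in scene.bodies.values()])
    M = np.zeros(ndof)
    rows, cols, vals = [], [], []
    coro = []

    def add_block(dofs: np.ndarray, Ke: np.ndarray) -> None:
        r = np.repeat(dofs, len(dofs))
        c = np.tile(dofs, len(dofs))
        rows.append(r)
        cols.append(c)
        vals.append(Ke.ravel())

    alpha = beta = None
    for name, body in scene.bodies.items():
        mat = body.material
        if alpha is None:
            alpha, beta = mat.rayleigh_alpha, mat.rayleigh_beta
        off = offsets[name]
        mesh = body.mesh
        mask = deactivated.get(name)
        if isinstance(mesh, TetMesh):
            tets = mesh.tetrahedra
        elif isinstance(mesh, HexMesh):
            raw = [t for h in mesh.hexahedra for t in _hex_to_tets(list(h))]
            for t in raw:  # orientation fix for the internal 6-tet split
                Dm = (mesh.nodes[t[1:]] - mesh.nodes[t[0]]).T
                if np.linalg.det(Dm) < 0:
                    t[2], t[3] = t[3], t[2]
            tets = np.array(raw, int)
            mask = None  # deactivation applies to drilled (tet) bodies only
        elif isinstance(mesh, TriShell):
            for ti, tri in enumerate(mesh.triangles):
                coords = mesh.nodes[tri]
                Ke = cst_membrane_stiffness(coords, mat.young_modulus,
                                            mat.poisson_ratio, mesh.thickness)
                dofs = np.concatenate(
                    [np.arange(3 * (off + v), 3 * (off + v) + 3) for v in tri])
                add_block(dofs, Ke)
                m = mat.density * mesh.thickness * mesh.areas[ti] / 3.0
                for v in tri:
                    M[3 * (off + v):3 * (off + v) + 3] += m
            continue
        else:  # pragma: no cover
            raise FemError(f"unsupported mesh type for body {name}")
        for ti, tet in enumerate(tets):
            if mask is not None and mask[ti]:
                continue
            coords = mesh.nodes[tet]
            Ke = tet_element_stiffness(coords, mat.young_modulus,
                                       mat.poisson_ratio)
            dofs = np.concatenate(
                [np.arange(3 * (off + v), 3 * (off + v) + 3) for v in tet])
            add_block(dofs, Ke)
            Dm = (coords[1:] - coords[0]).T
            vol = np.linalg.det(Dm) / 6.0
            m = mat.density * vol / 4.0
            for v in tet:
                M[3 * (off + v):3 * (off + v) + 3] += m
            if isinstance(mesh, TetMesh):
                coro.append((dofs, Ke, np.linalg.inv(Dm), x0[dofs].copy()))

    # springs: k d d^T along the (rest) direction
    for s in scene.springs:
        if s.tag in exclude_spring_tags:
            continue
        body_a, ia = s.a
        da = np.arange(3 * (offsets[body_a] + ia), 3 * (offsets[body_a] + ia) + 3)
        pa = scene.bodies[body_a].mesh.nodes[ia]
        if isinstance(s.b, tuple):
            body_b, ib = s.b
            db = np.arange(3 * (offsets[body_b] + ib),
                           3 * (offsets[body_b] + ib) + 3)
            pb = scene.bodies[body_b].mesh.nodes[ib]
        else:
            db, pb = None, np.asarray(s.b, float)
        if s.direction is not None:
            d = s.direction
        else:
            delta = pb - pa
            L = np.linalg.norm(delta)
            if L < 1e-12:
                raise FemError("zero-length spring without explicit direction")
            d = delta / L
        kblock = s.stiffness * np.outer(d, d)
        if db is None:
            add_block(da, kblock)
        else:
            dofs = np.concatenate([da, db])
            K4 = np.block([[kblock, -kblock], [-kblock, kblock]])
            add_block(dofs, K4)

    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof)).tocsr()
    C = rayleigh_damping(M, K, alpha, beta)

    free = np.ones(ndof, bool)
    for name, idx in scene.fixed_nodes.items():
        for i in np.asarray(idx, int):
            free[3 * (offsets[name] + i):3 * (offsets[name] + i) + 3] = False

    kdiag = K.diagonal()
    bad = free & (M <= 0) & (kdiag <= 0)
    if bad.any():
        # nodes orphaned by element deactivation (drilled away) are frozen;
        # anything else is a modelling error
        for name in deactivated:
            off, cnt = offsets[name], counts[name]
            sl = slice(3 * off, 3 * (off + cnt))
            free[sl] &= ~bad[sl]
            bad[sl] = False
        if bad.any():
            raise FemError("free degree of freedom with no mass and no "
                           "stiffness (isolated unconstrained body?)")

    return SystemMatrices(M=M, K=K, C=C, free=free, x0=x0,
                          node_offsets=offsets, node_counts=counts,
                          corotational_elements=coro)


def backward_euler_step(state: MechState, sys: SystemMatrices,
                        external_forces: np.ndarray | None = None,
                        contact_impulses: np.ndarray | None = None,
                        settings: SolverSettings | None = None) -> MechState:
    """One implicit backward-Euler step.

    Solves (M + dt C + dt^2 K) dv = dt (f_ext + f_el(x) - C v - dt K v) + p
    for the velocity update (p = contact impulses), then advances positions
    by dt * v_new.  Fixed dofs stay put.
    """
    settings = settings or SolverSettings()
    dt = settings.time_step
    f_ext = (np.zeros(sys.ndof) if external_forces is None
             else np.asarray(external_forces, float))
    p = (np.zeros(sys.ndof) if contact_impulses is None
         else np.asarray(contact_impulses, float))
    f_el = sys.elastic_force(state.positions, settings.corotational)
    rhs = dt * (f_ext + f_el - sys.C @ state.velocities
                - dt * (sys.K @ state.velocities)) + p
    dv = sys.solve(dt, rhs)
    v_new = state.velocities + dv
    v_new[~sys.free] = 0.0
    x_new = state.positions + dt * v_new
    x_new[~sys.free] = state.positions[~sys.free]
    return MechState(x_new, v_new, state.time + dt)


def harmonic_response(M, K, C, force: np.ndarray,
                      omegas: np.ndarray) -> np.ndarray:
    """Steady-state response u(w) of (K + i w C - w^2 M) u = f per circular
    frequency; M may be a diagonal vector.  Returns (n_freq, ndof) complex."""
    Md = sp.diags(M) if np.ndim(M) == 1 else M
    out = np.zeros((len(omegas), force.size), complex)
    for i, w in enumerate(omegas):
        A = (K + 1j * w * C - w * w * Md).tocsc()
        try:
            out[i] = spla.spsolve(A, force.astype(complex))
        except RuntimeError as exc:
            raise FemError(f"singular harmonic system at omega={w}") from exc
    return out


def static_solve(sys: SystemMatrices, force: np.ndarray) -> np.ndarray:
    """Static displacement K u = f on the free dofs."""
    Kff = sys.K[np.ix_(sys.free, sys.free)].tocsc()
    u = np.zeros(sys.ndof)
    try:
        u[sys.free] = spla.spsolve(Kff, force[sys.free])
    except RuntimeError as exc:
        raise FemError("singular stiffness (unconstrained system)") from exc
    if not np.isfinite(u).all():
        raise FemError("singular stiffness (unconstrained system)")
    return u
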