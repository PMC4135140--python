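"""Procedural middle-ear scene construction, primitive signed-distance fields,
and basic mesh measures.

The synthetic anatomy is a parametric stand-in for a patient geometry: an
elliptic stapes footplate (2.8 x 1.52 mm laterally), a simplified stapes
superstructure, incus and malleus bodies, a tympanic-membrane disc, joint and
annular-ligament springs, a 0.4 x 4.5 mm piston prosthesis and the rigid tools
(0.6 mm spherical burr, microforceps tip, blocking rod, piston grasper).

Axis convention (right-handed): X = anterior-posterior, Y = superior-inferior,
Z = lateral-medial with +Z pointing medially (toward the inner ear).  All mesh
coordinates are stored in metres; configuration files use millimetres.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

MM = 1e-3  # metres per millimetre

__all__ = [
    "TetMesh", "TriShell", "HexMesh", "Material", "Spring", "SpringSet",
    "ToolShape", "RigidPose", "Body", "Scene", "ConfigurationError",
    "ConstructionError", "default_config", "build_scene", "primitive_sdf",
    "mesh_volume", "sdf_sphere", "sdf_ellipsoid", "sdf_capsule",
    "sdf_cylinder", "sdf_box", "sdf_elliptic_plate",
]


class ConfigurationError(ValueError):
    """Raised for invalid scene configuration values."""


class ConstructionError(ValueError):
    """Raised when a constructed mesh violates its invariants."""


# ---------------------------------------------------------------------------
# mesh containers
# ---------------------------------------------------------------------------

def _tet_signed_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a, b, c, d = (nodes[tets[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


@dataclass
class TetMesh:
    """Tetrahedral volume mesh (ossicles)."""

    nodes: np.ndarray            # (n, 3) metres
    tetrahedra: np.ndarray       # (m, 4) node indices
    body_label: str = ""

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tetrahedra = np.asarray(self.tetrahedra, dtype=int)
        self.validate()

    def validate(self) -> None:
        if self.tetrahedra.size and self.tetrahedra.max() >= len(self.nodes):
            raise ConstructionError("tetrahedron node index out of range")
        if self.tetrahedra.min(initial=0) < 0:
            raise ConstructionError("negative node index")
        vols = _tet_signed_volumes(self.nodes, self.tetrahedra)
        if np.any(vols <= 0):
            raise ConstructionError(
                f"{int(np.sum(vols <= 0))} tetrahedra with non-positive volume"
            )
        key = np.sort(self.tetrahedra, axis=1)
        if len(np.unique(key, axis=0)) != len(key):
            raise ConstructionError("duplicate tetrahedra")

    @property
    def volumes(self) -> np.ndarray:
        return _tet_signed_volumes(self.nodes, self.tetrahedra)


@dataclass
class TriShell:
    """Triangle shell mesh with a membrane thickness (tympanic membrane)."""

    nodes: np.ndarray        # (n, 3) metres
    triangles: np.ndarray    # (m, 3) node indices
    thickness: float         # metres

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.thickness <= 0:
            raise ConstructionError("membrane thickness must be positive")
        if np.any(self.areas <= 0):
            raise ConstructionError("triangle with zero area")

    @property
    def areas(self) -> np.ndarray:
        a, b, c = (self.nodes[self.triangles[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


@dataclass
class HexMesh:
    """Hexahedral mesh in VTK corner ordering (piston prosthesis)."""

    nodes: np.ndarray        # (n, 3) metres
    hexahedra: np.ndarray    # (m, 8) node indices

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.hexahedra = np.asarray(self.hexahedra, dtype=int)
        if np.any(self.volumes <= 0):
            raise ConstructionError("hexahedron with non-positive volume")

    @property
    def volumes(self) -> np.ndarray:
        return np.array([_hex_volume(self.nodes[h]) for h in self.hexahedra])


_HEX_FACES = [  # VTK ordering, outward normals
    (0, 3, 2, 1), (4, 5, 6, 7), (0, 1, 5, 4),
    (1, 2, 6, 5), (2, 3, 7, 6), (3, 0, 4, 7),
]


def _hex_volume(corners: np.ndarray) -> float:
    """Volume of one hexahedron by the divergence theorem over its
    triangulated faces (exact for planar faces)."""
    vol = 0.0
    for f in _HEX_FACES:
        q = corners[list(f)]
        for tri in ((q[0], q[1], q[2]), (q[0], q[2], q[3])):
            vol += np.dot(tri[0], np.cross(tri[1], tri[2])) / 6.0
    return vol


@dataclass
class Material:
    """Isotropic linear-elastic material with Rayleigh damping coefficients.

    C = rayleigh_alpha * M + rayleigh_beta * K.
    """

    young_modulus: float       # Pa
    poisson_ratio: float
    density: float             # kg/m^3
    rayleigh_alpha: float = 0.0    # 1/s
    rayleigh_beta: float = 1.0e-4  # s

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ConfigurationError("young_modulus must be > 0")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ConfigurationError("poisson_ratio must be in [0, 0.5)")
        if self.density <= 0:
            raise ConfigurationError("density must be > 0")
        if self.rayleigh_alpha < 0 or self.rayleigh_beta < 0:
            raise ConfigurationError("Rayleigh coefficients must be >= 0")


@dataclass
class Spring:
    """Linear spring between a body node and either another body node or a
    fixed world anchor.

    For zero-length grounding springs the acting direction cannot be inferred
    from the endpoints, so it may be given explicitly.
    """

    a: tuple[str, int]                       # (body name, node index)
    b: tuple[str, int] | np.ndarray          # node ref or anchor point (m)
    stiffness: float                         # N/m
    rest_length: float = 0.0                 # m
    direction: np.ndarray | None = None      # unit vector, optional
    tag: str = ""

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ConfigurationError("spring stiffness must be > 0")
        if isinstance(self.b, tuple) and self.b == self.a:
            raise ConfigurationError("spring endpoints must be distinct")
        if self.direction is not None:
            self.direction = np.asarray(self.direction, float)
            self.direction = self.direction / np.linalg.norm(self.direction)


@dataclass
class SpringSet:
    springs: list[Spring] = field(default_factory=list)

    def __iter__(self):
        return iter(self.springs)

    def __len__(self) -> int:
        return len(self.springs)

    def add(self, spring: Spring) -> None:
        self.springs.append(spring)

    def without_tag(self, tag: str) -> "SpringSet":
        return SpringSet([s for s in self.springs if s.tag != tag])


# ---------------------------------------------------------------------------
# rigid poses and tools
# ---------------------------------------------------------------------------

@dataclass
class RigidPose:
    """Rigid transform: world point = R(q) @ local + position."""

    position: np.ndarray                     # (3,) m
    quaternion: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))  # w,x,y,z

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float)
        self.quaternion = np.asarray(self.quaternion, float)
        n = np.linalg.norm(self.quaternion)
        if not np.isfinite(self.position).all() or not np.isfinite(n) or n == 0:
            raise ConfigurationError("pose must be finite with nonzero quaternion")
        self.quaternion = self.quaternion / n

    @property
    def rotation(self) -> Rotation:
        w, x, y, z = self.quaternion
        return Rotation.from_quat([x, y, z, w])

    def transform(self, pts: np.ndarray) -> np.ndarray:
        return self.rotation.apply(np.atleast_2d(pts)) + self.position

    def inverse_transform(self, pts: np.ndarray) -> np.ndarray:
        return self.rotation.inv().apply(np.atleast_2d(pts) - self.position)


_TOOL_KINDS = ("sphere_burr", "forceps_tip", "rod", "piston_grasper")


@dataclass
class ToolShape:
    """Analytic rigid tool with a signed-distance function in its local frame.

    Local frames: the burr is a sphere centred at the origin; rod and forceps
    are capsules running from the origin along +Z; the piston grasper carries
    the prosthesis shaft hanging along -Z from the grasp point plus the loop
    wall (a short capsule along Y at the origin) that pushes on the incus
    long process during crimping.
    """

    kind: str
    dims: dict[str, float]   # metres

    def __post_init__(self) -> None:
        if self.kind not in _TOOL_KINDS:
            raise ConfigurationError(f"unknown tool kind {self.kind!r}")
        for k, v in self.dims.items():
            if v <= 0:
                raise ConfigurationError(f"tool dimension {k} must be > 0")

    def sdf_local(self, pts: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(pts)
        d = self.dims
        if self.kind == "sphere_burr":
            return sdf_sphere(p, np.zeros(3), d["diameter"] / 2)
        if self.kind == "rod":
            return sdf_capsule(p, np.zeros(3), np.array([0, 0, d["length"]]),
                               d["diameter"] / 2)
        if self.kind == "forceps_tip":
            return sdf_capsule(p, np.zeros(3), np.array([0, 0, d["length"]]),
                               d["tip_radius"])
        # piston grasper carrying the prosthesis: shaft capsule hanging -Z
        # plus the crimp loop as a U-shaped pocket of flat walls (back wall
        # whose inner face at local x=0 pushes the incus long process, two
        # side walls gripping it laterally like the real loop aperture)
        w = d["loop_half_width"]
        a = d["loop_aperture_half_width"]
        thick = d["wall_thickness"]
        hh = d["wall_half_height"]
        depth = d["loop_depth"]
        shaft = sdf_capsule(
            p, np.array([-thick - d["shaft_radius"], 0, 0]),
            np.array([-thick - d["shaft_radius"], 0, -d["shaft_length"]]),
            d["shaft_radius"])
        back = sdf_box(p, np.array([-thick / 2, 0, 0]),
                       np.array([thick / 2, w, hh]))
        side_p = sdf_box(p, np.array([depth / 2, a + thick / 2, 0]),
                         np.array([depth / 2, thick / 2, hh]))
        side_m = sdf_box(p, np.array([depth / 2, -a - thick / 2, 0]),
                         np.array([depth / 2, thick / 2, hh]))
        return np.minimum(np.minimum(shaft, back),
                          np.minimum(side_p, side_m))

    def sdf(self, pts_world: np.ndarray, pose: RigidPose) -> np.ndarray:
        return self.sdf_local(pose.inverse_transform(pts_world))

    def bounding_radius(self) -> float:
        d = self.dims
        if self.kind == "sphere_burr":
            return d["diameter"] / 2
        if self.kind == "rod":
            return d["length"] + d["diameter"] / 2
        if self.kind == "forceps_tip":
            return d["length"] + d["tip_radius"]
        return max(d["shaft_length"] + d["wall_thickness"]
                   + 2 * d["shaft_radius"],
                   d["loop_half_width"] + d["wall_thickness"],
                   d["loop_aperture_half_width"] + d["wall_thickness"],
                   d["loop_depth"])


# ---------------------------------------------------------------------------
# analytic signed-distance primitives (negative inside)
# ---------------------------------------------------------------------------

def sdf_sphere(p, center, radius):
    return np.linalg.norm(np.atleast_2d(p) - center, axis=1) - radius


def sdf_capsule(p, a, b, radius):
    p = np.atleast_2d(p)
    ab = np.asarray(b, float) - np.asarray(a, float)
    t = np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0)
    closest = np.asarray(a) + t[:, None] * ab
    return np.linalg.norm(p - closest, axis=1) - radius


def sdf_box(p, center, half_extents):
    q = np.abs(np.atleast_2d(p) - center) - np.asarray(half_extents, float)
    outside = np.linalg.norm(np.maximum(q, 0.0), axis=1)
    inside = np.minimum(q.max(axis=1), 0.0)
    return outside + inside


def sdf_cylinder(p, center, radius, half_height):
    """Finite cylinder, axis along Z (exact SDF)."""
    p = np.atleast_2d(p) - center
    dr = np.linalg.norm(p[:, :2], axis=1) - radius
    dz = np.abs(p[:, 2]) - half_height
    q = np.stack([dr, dz], axis=1)
    outside = np.linalg.norm(np.maximum(q, 0.0), axis=1)
    inside = np.minimum(q.max(axis=1), 0.0)
    return outside + inside


def _ellipse_distance(p2: np.ndarray, ab: np.ndarray) -> np.ndarray:
    """Unsigned distance from 2-D points to an axis-aligned ellipse boundary,
    by bisection on the Lagrange parameter of the closest-point problem."""
    q = np.abs(p2)
    a2 = ab ** 2
    inside = np.sum((q / ab) ** 2, axis=1) < 1.0
    # root of f(t) = sum (a_i q_i / (t + a_i^2))^2 - 1 in (-min a_i^2, inf)
    lo = np.full(len(q), -np.min(a2) * (1 - 1e-12))
    hi = np.full(len(q), np.max(ab) * (np.linalg.norm(q, axis=1) + np.max(ab)))
    for _ in range(100):
        t = 0.5 * (lo + hi)
        f = np.sum((ab * q / (t[:, None] + a2)) ** 2, axis=1) - 1.0
        hi = np.where(f < 0, t, hi)
        lo = np.where(f >= 0, t, lo)
    t = 0.5 * (lo + hi)
    closest = a2 * q / (t[:, None] + a2)
    d = np.linalg.norm(q - closest, axis=1)
    # points at the exact centre: nearest boundary point is the minor vertex
    at_center = np.linalg.norm(q, axis=1) < 1e-300
    d[at_center] = np.min(ab)
    return np.where(inside, -d, d)


def sdf_ellipsoid(p, center, semi_axes):
    """Signed distance to an axis-aligned ellipsoid (bisection on the
    closest-point parameter; exact up to the iteration tolerance)."""
    q = np.abs(np.atleast_2d(p) - center)
    ab = np.asarray(semi_axes, float)
    a2 = ab ** 2
    inside = np.sum((q / ab) ** 2, axis=1) < 1.0
    lo = np.full(len(q), -np.min(a2) * (1 - 1e-12))
    hi = np.full(len(q), np.max(ab) * (np.linalg.norm(q, axis=1) + np.max(ab)))
    for _ in range(100):
        t = 0.5 * (lo + hi)
        f = np.sum((ab * q / (t[:, None] + a2)) ** 2, axis=1) - 1.0
        hi = np.where(f < 0, t, hi)
        lo = np.where(f >= 0, t, lo)
    t = 0.5 * (lo + hi)
    closest = a2 * q / (t[:, None] + a2)
    d = np.linalg.norm(q - closest, axis=1)
    at_center = np.linalg.norm(q, axis=1) < 1e-300
    d[at_center] = np.min(ab)
    return np.where(inside, -d, d)


def sdf_elliptic_plate(p, center, semi_axes_xy, half_thickness):
    """Elliptic plate: intersection of an elliptic cylinder (axis Z) and a
    slab.  Exact except within a corner region near the rim edge."""
    p = np.atleast_2d(p) - center
    d_ell = _ellipse_distance(p[:, :2], np.asarray(semi_axes_xy, float))
    d_slab = np.abs(p[:, 2]) - half_thickness
    q = np.stack([d_ell, d_slab], axis=1)
    outside = np.linalg.norm(np.maximum(q, 0.0), axis=1)
    inside = np.minimum(q.max(axis=1), 0.0)
    return outside + inside


_SHAPE_FNS = {
    "sphere": lambda p, s: sdf_sphere(p, s["center"], s["radius"]),
    "ellipsoid": lambda p, s: sdf_ellipsoid(p, s["center"], s["semi_axes"]),
    "capsule": lambda p, s: sdf_capsule(p, s["a"], s["b"], s["radius"]),
    "cylinder": lambda p, s: sdf_cylinder(p, s["center"], s["radius"],
                                          s["half_height"]),
    "box": lambda p, s: sdf_box(p, s["center"], s["half_extents"]),
    "plate": lambda p, s: sdf_elliptic_plate(p, s["center"], s["semi_axes"],
                                             s["half_thickness"]),
}


def analytic_sdf(shape: dict, points: np.ndarray) -> np.ndarray:
    """Evaluate the analytic signed distance of `shape` at `points`."""
    kind = shape.get("kind")
    if kind not in _SHAPE_FNS:
        raise ConfigurationError(f"unknown shape kind {kind!r}")
    return _SHAPE_FNS[kind](points, shape)


def primitive_sdf(shape: dict, grid: dict):
    """Sample an analytic primitive onto a regular voxel grid.

    `grid` gives either origin/spacing/dims or bounds/spacing.  Returns an
    SDFGrid with the convention negative = inside material.
    """
    from .carving import SDFGrid

    spacing = float(grid["spacing"])
    if spacing <= 0:
        raise ConfigurationError("grid spacing must be > 0")
    if "bounds" in grid:
        lo, hi = (np.asarray(b, float) for b in grid["bounds"])
        dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
        origin = lo
    else:
        origin = np.asarray(grid["origin"], float)
        dims = np.asarray(grid["dims"], int)
    axes = [origin[i] + spacing * np.arange(dims[i]) for i in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    values = analytic_sdf(shape, pts).reshape(dims)
    return SDFGrid(origin=origin, spacing=spacing, values=values)


# ---------------------------------------------------------------------------
# mesh volume
# ---------------------------------------------------------------------------

def mesh_volume(mesh) -> float:
    """Total enclosed volume of a mesh, in the cube of its coordinate units.

    For a TriShell the surface must be closed and consistently oriented;
    an open surface raises ConstructionError.
    """
    if isinstance(mesh, TetMesh):
        return float(np.sum(mesh.volumes))
    if isinstance(mesh, HexMesh):
        return float(np.sum(mesh.volumes))
    if isinstance(mesh, TriShell):
        tris = mesh.triangles
        edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]],
                                tris[:, [2, 0]]])
        und = np.sort(edges, axis=1)
        _, counts = np.unique(und, axis=0, return_counts=True)
        if np.any(counts != 2):
            raise ConstructionError("surface is not closed (boundary edges)")
        a, b, c = (mesh.nodes[tris[:, i]] for i in range(3))
        vol = np.sum(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0
        return float(abs(vol))
    raise TypeError(f"unsupported mesh type {type(mesh).__name__}")


# ---------------------------------------------------------------------------
# structured mesh builders
# ---------------------------------------------------------------------------

_CUBE_TETS = [(0, 1, 3, 7), (0, 3, 2, 7), (0, 2, 6, 7),
              (0, 6, 4, 7), (0, 4, 5, 7), (0, 5, 1, 7)]
# corner v = 4*i + 2*j + k over the (i, j, k) cell-offset bits


def _grid_tets(node_index, nx, ny, nz, nodes):
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = [node_index(i + di, j + dj, k + dk)
                     for di in (0, 1) for dj in (0, 1) for dk in (0, 1)]
                for t in _CUBE_TETS:
                    tet = [c[t[0]], c[t[1]], c[t[2]], c[t[3]]]
                    v = _tet_signed_volumes(nodes, np.array([tet]))[0]
                    if v < 0:
                        tet[2], tet[3] = tet[3], tet[2]
                    tets.append(tet)
    return np.array(tets, dtype=int)


def box_tet_mesh(center, size, divisions, label="") -> TetMesh:
    """Axis-aligned box filled with a structured 6-tet-per-cell grid."""
    nx, ny, nz = divisions
    center = np.asarray(center, float)
    size = np.asarray(size, float)
    ax = [np.linspace(-size[i] / 2, size[i] / 2, d + 1)
          for i, d in enumerate(divisions)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    nodes = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1) + center

    def idx(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    return TetMesh(nodes, _grid_tets(idx, nx, ny, nz, nodes), label)


def _square_to_ellipse(u, v, a, b):
    """Smooth area-preserving-ish map of the square [-1,1]^2 onto an ellipse
    with semi-axes a, b; boundary extremes map to exactly +-a, +-b."""
    x = a * u * np.sqrt(np.maximum(1.0 - v ** 2 / 2.0, 0.0))
    y = b * v * np.sqrt(np.maximum(1.0 - u ** 2 / 2.0, 0.0))
    return x, y


def elliptic_plate_tet_mesh(center, semi_axes_xy, thickness, divisions,
                            label="footplate") -> TetMesh:
    """Elliptic plate (footplate) as a structured tetrahedral mesh built by
    mapping a square grid onto the ellipse cross-section and extruding."""
    nu, nv, nw = divisions
    a, b = semi_axes_xy
    u = np.linspace(-1, 1, nu + 1)
    v = np.linspace(-1, 1, nv + 1)
    w = np.linspace(-thickness / 2, thickness / 2, nw + 1)
    uu, vv, ww = np.meshgrid(u, v, w, indexing="ij")
    x, y = _square_to_ellipse(uu, vv, a, b)
    nodes = np.stack([x.ravel(), y.ravel(), ww.ravel()], axis=1) + center

    def idx(i, j, k):
        return (i * (nv + 1) + j) * (nw + 1) + k

    return TetMesh(nodes, _grid_tets(idx, nu, nv, nw, nodes), label)


def disc_tri_shell(center, radius, divisions, thickness) -> TriShell:
    """Flat disc (tympanic membrane) in the XY plane, square-to-disc mapped."""
    n = divisions
    u = np.linspace(-1, 1, n + 1)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    x, y = _square_to_ellipse(uu, vv, radius, radius)
    nodes = np.stack([x.ravel(), y.ravel(), np.zeros_like(x.ravel())],
                     axis=1) + center
    tris = []
    for i in range(n):
        for j in range(n):
            p00 = i * (n + 1) + j
            p01 = p00 + 1
            p10 = p00 + (n + 1)
            p11 = p10 + 1
            tris.append([p00, p10, p11])
            tris.append([p00, p11, p01])
    return TriShell(nodes, np.array(tris, int), thickness)


def box_hex_mesh(center, size, divisions) -> HexMesh:
    """Axis-aligned box of hexahedra in VTK corner ordering."""
    nx, ny, nz = divisions
    center = np.asarray(center, float)
    size = np.asarray(size, float)
    ax = [np.linspace(-size[i] / 2, size[i] / 2, d + 1)
          for i, d in enumerate(divisions)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    nodes = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1) + center

    def idx(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    hexes = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                hexes.append([idx(i, j, k), idx(i + 1, j, k),
                              idx(i + 1, j + 1, k), idx(i, j + 1, k),
                              idx(i, j, k + 1), idx(i + 1, j, k + 1),
                              idx(i + 1, j + 1, k + 1), idx(i, j + 1, k + 1)])
    return HexMesh(nodes, np.array(hexes, int))


# ---------------------------------------------------------------------------
# scene
# ---------------------------------------------------------------------------

@dataclass
class Body:
    name: str
    mesh: TetMesh | TriShell | HexMesh
    material: Material


@dataclass
class Scene:
    """All anatomy bodies, springs, boundary conditions, tools and the
    stapedotomy target."""

    bodies: dict[str, Body]
    springs: SpringSet
    fixed_nodes: dict[str, np.ndarray]           # body -> node indices
    tools: dict[str, tuple[ToolShape, RigidPose]]
    target_point: np.ndarray                     # m, on the footplate surface
    speculum_diameter: float = 6.0 * MM          # m, visual aperture only
    named_nodes: dict[str, tuple[str, int]] = field(default_factory=dict)
    sdf_grids: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def node_position(self, name: str) -> np.ndarray:
        body, idx = self.named_nodes[name]
        return self.bodies[body].mesh.nodes[idx]


def default_config() -> dict:
    """Default scene configuration.  Lengths in mm, moduli in Pa, densities
    in kg/m^3, stiffnesses in N/m."""
    return {
        "geometry": {
            "footplate": {"x_extent": 2.8, "y_extent": 1.52,
                          "thickness": 0.25, "divisions": [8, 6, 2]},
            "superstructure": {"size": [0.6, 0.6, 1.2],
                               "divisions": [2, 2, 3]},
            "incus": {"size": [0.5, 0.5, 2.6], "divisions": [2, 2, 6],
                      "center": [0.35, 0.0, -2.7]},
            "malleus": {"size": [0.6, 0.6, 1.5], "divisions": [2, 2, 3],
                        "center": [-1.0, 0.0, -4.25]},
            "membrane": {"radius": 4.0, "thickness": 0.074, "divisions": 8,
                         "center": [-1.0, 0.0, -5.0]},
            "prosthesis": {"diameter": 0.4, "length": 4.5,
                           "divisions": [1, 1, 9],
                           "initial_position": [-0.7, 0.0, -3.65]},
            "speculum_diameter": 6.0,
        },
        "materials": {
            "ossicle": {"young_modulus": 14.1e9, "poisson_ratio": 0.3,
                        "density": 2.2e3, "rayleigh_alpha": 0.0,
                        "rayleigh_beta": 1.0e-4},
            "membrane": {"young_modulus": 32e6, "poisson_ratio": 0.3,
                         "density": 1.2e3, "rayleigh_alpha": 0.0,
                         "rayleigh_beta": 1.0e-4},
            "prosthesis": {"young_modulus": 344e6, "poisson_ratio": 0.3,
                           "density": 4.5e3, "rayleigh_alpha": 0.0,
                           "rayleigh_beta": 1.0e-4},
        },
        "springs": {
            "annular_stiffness": 100.0,
            "annular_fixation_factor": 1.0,   # >1 emulates otosclerosis
            "joint_stiffness": 2000.0,
            "membrane_attach_stiffness": 500.0,
            "membrane_tension_stiffness": 50.0,
            "grasp_stiffness": 50.0,
            "grasp_damping": 0.5,
            # effective normal stiffness of tool contacts: the prosthesis
            # (thin titanium loop/shaft) is far softer than a steel rod
            # pressed on bone
            "prosthesis_contact_stiffness": 5.0e3,
            "rigid_contact_stiffness": 1.0e6,
        },
        "tools": {
            "burr": {"diameter": 0.6},
            "rod": {"diameter": 0.6, "length": 8.0},
            "forceps": {"tip_radius": 0.15, "length": 1.0},
            "grasper": {"shaft_radius": 0.2, "shaft_length": 4.5,
                        "loop_half_width": 0.6, "wall_thickness": 0.5,
                        "wall_half_height": 0.3,
                        "loop_aperture_half_width": 0.27, "loop_depth": 0.9},
        },
        "sdf": {"spacing": 0.02, "padding": 0.3},
        "solver": {"time_step": 0.04, "linear_tolerance": 1e-10,
                   "corotational": False, "contact_iterations": 400,
                   "contact_tolerance": 1e-8},
    }


def _merge_config(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in (override or {}).items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigurationError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge_config(defaults[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


def _nearest_pairs(sub_nodes, sub_idx, target_nodes):
    """For each node index in sub_idx (positions sub_nodes), the nearest node
    index of target_nodes."""
    d = np.linalg.norm(sub_nodes[:, None, :] - target_nodes[None, :, :],
                       axis=2)
    return list(zip(sub_idx, d.argmin(axis=1)))


def build_scene(config: dict | None = None) -> Scene:
    """Construct the synthetic middle-ear scene.

    Deterministic given the configuration: the same config always produces
    the same meshes, springs and tool poses.
    """
    cfg = _merge_config(default_config(), config or {})
    g, mats, spr, tl = (cfg["geometry"], cfg["materials"], cfg["springs"],
                        cfg["tools"])

    for name, sec in (("footplate", g["footplate"]),):
        for key in ("x_extent", "y_extent", "thickness"):
            if sec[key] <= 0:
                raise ConfigurationError(f"geometry.{name}.{key} must be > 0")

    materials = {k: Material(**v) for k, v in mats.items()}

    fp = g["footplate"]
    a, b = fp["x_extent"] / 2 * MM, fp["y_extent"] / 2 * MM
    t_fp = fp["thickness"] * MM
    footplate = elliptic_plate_tet_mesh(
        np.zeros(3), (a, b), t_fp, fp["divisions"], "footplate")

    ss = g["superstructure"]
    ss_size = np.asarray(ss["size"], float) * MM
    ss_center = np.array([0.0, 0.0, -t_fp / 2 - ss_size[2] / 2])
    superstructure = box_tet_mesh(ss_center, ss_size, ss["divisions"],
                                  "superstructure")

    inc = g["incus"]
    incus = box_tet_mesh(np.asarray(inc["center"]) * MM,
                         np.asarray(inc["size"]) * MM, inc["divisions"],
                         "incus")

    mal = g["malleus"]
    malleus = box_tet_mesh(np.asarray(mal["center"]) * MM,
                           np.asarray(mal["size"]) * MM, mal["divisions"],
                           "malleus")

    mem = g["membrane"]
    membrane = disc_tri_shell(np.asarray(mem["center"]) * MM,
                              mem["radius"] * MM, mem["divisions"],
                              mem["thickness"] * MM)

    pr = g["prosthesis"]
    pros_size = np.array([pr["diameter"], pr["diameter"], pr["length"]]) * MM
    prosthesis = box_hex_mesh(np.zeros(3), pros_size, pr["divisions"])
    pros_pose0 = RigidPose(np.asarray(pr["initial_position"]) * MM)
    prosthesis.nodes = prosthesis.nodes + pros_pose0.position

    bodies = {
        "footplate": Body("footplate", footplate, materials["ossicle"]),
        "superstructure": Body("superstructure", superstructure,
                               materials["ossicle"]),
        "incus": Body("incus", incus, materials["ossicle"]),
        "malleus": Body("malleus", malleus, materials["ossicle"]),
        "membrane": Body("membrane", membrane, materials["membrane"]),
        "prosthesis": Body("prosthesis", prosthesis, materials["prosthesis"]),
    }

    springs = SpringSet()

    # annular ligament: rim nodes of the footplate, sprung radially and
    # axially against fixed anchors (elastic foundation around the oval window)
    k_al = spr["annular_stiffness"] * spr["annular_fixation_factor"]
    r2 = (footplate.nodes[:, 0] / a) ** 2 + (footplate.nodes[:, 1] / b) ** 2
    rim = np.where(r2 > 0.98)[0]
    for i in rim:
        p = footplate.nodes[i]
        radial = np.array([p[0] / a ** 2, p[1] / b ** 2, 0.0])
        radial /= np.linalg.norm(radial)
        springs.add(Spring(("footplate", int(i)), p + radial * 0.1 * MM,
                           k_al, 0.1 * MM, direction=radial, tag="annular"))
        springs.add(Spring(("footplate", int(i)), p + np.array([0, 0, 0.1 * MM]),
                           k_al, 0.1 * MM, direction=np.array([0, 0, 1.0]),
                           tag="annular"))

    k_joint = spr["joint_stiffness"]

    def join(body_a, mesh_a, sel_a, body_b, mesh_b, tag, k=None):
        # joints are isotropic attachments (one spring per axis), so the
        # capsule resists all relative motion, not just along the gap
        k = k_joint if k is None else k
        for ia, ib in _nearest_pairs(mesh_a.nodes[sel_a], sel_a, mesh_b.nodes):
            L = np.linalg.norm(mesh_b.nodes[ib] - mesh_a.nodes[ia])
            for axis in np.eye(3):
                springs.add(Spring((body_a, int(ia)), (body_b, int(ib)),
                                   k, L, direction=axis, tag=tag))

    # stapes superstructure base -> footplate (fused in reality; stiff springs)
    base = np.where(np.isclose(superstructure.nodes[:, 2],
                               superstructure.nodes[:, 2].max()))[0]
    join("superstructure", superstructure, base, "footplate", footplate,
         "stapes_base")
    # incudostapedial joint: incus tip end -> superstructure head
    tip_sel = np.where(np.isclose(incus.nodes[:, 2], incus.nodes[:, 2].max()))[0]
    join("incus", incus, tip_sel, "superstructure", superstructure, "i_s_joint")
    # incudomalleolar joint: incus lateral end -> malleus
    top_sel = np.where(np.isclose(incus.nodes[:, 2], incus.nodes[:, 2].min()))[0]
    join("incus", incus, top_sel, "malleus", malleus, "i_m_joint")
    # malleus manubrium -> membrane
    man = np.where(np.isclose(malleus.nodes[:, 2], malleus.nodes[:, 2].min()))[0]
    join("malleus", malleus, man, "membrane", membrane, "umbo",
         k=spr["membrane_attach_stiffness"])

    # transverse elastic foundation on the membrane: a constant-strain
    # membrane has no bending stiffness, so its resistance to out-of-plane
    # (z) load comes from curvature/prestress in reality; a weak per-node
    # tension spring stands in for that here
    k_ten = spr["membrane_tension_stiffness"]
    interior = np.setdiff1d(np.arange(len(membrane.nodes)), [])
    for i in interior:
        p = membrane.nodes[i]
        springs.add(Spring(("membrane", int(i)), p + np.array([0, 0, 0.1 * MM]),
                           k_ten, 0.1 * MM, direction=np.array([0, 0, 1.0]),
                           tag="membrane_tension"))

    # grasper anchor springs hold the free-floating prosthesis for static
    # analyses; procedure runs replace them with the live grasp spring
    grasp_sel = np.where(np.isclose(prosthesis.nodes[:, 2],
                                    prosthesis.nodes[:, 2].max()))[0]
    for i in grasp_sel:
        p = prosthesis.nodes[i]
        for axis in np.eye(3):
            springs.add(Spring(("prosthesis", int(i)), p + axis * 0.1 * MM,
                               spr["grasp_stiffness"], 0.1 * MM,
                               direction=axis, tag="grasp_anchor"))

    # fixed boundary: tympanic annulus (membrane rim)
    rr = np.linalg.norm(membrane.nodes[:, :2] - np.asarray(mem["center"][:2]) * MM,
                        axis=1)
    mem_rim = np.where(rr > 0.98 * mem["radius"] * MM)[0]
    fixed_nodes = {"membrane": mem_rim}

    tools = {
        "burr": (ToolShape("sphere_burr",
                           {"diameter": tl["burr"]["diameter"] * MM}),
                 RigidPose(np.array([0.0, 0.0, -3.0 * MM]))),
        "rod": (ToolShape("rod", {"diameter": tl["rod"]["diameter"] * MM,
                                  "length": tl["rod"]["length"] * MM}),
                RigidPose(np.array([2.0 * MM, 0.0, -3.0 * MM]))),
        "forceps": (ToolShape("forceps_tip",
                              {"tip_radius": tl["forceps"]["tip_radius"] * MM,
                               "length": tl["forceps"]["length"] * MM}),
                    RigidPose(np.array([-2.0 * MM, 0.0, -3.0 * MM]))),
        # the grasper holds the prosthesis at its loop (top) end, so the
        # loop pocket sits at the grasper origin
        "grasper": (ToolShape("piston_grasper",
                              {k: v * MM for k, v in tl["grasper"].items()}),
                    RigidPose(pros_pose0.position
                              + np.array([0, 0, pros_size[2] / 2]))),
    }

    # named nodes: incus long-process tip (medial face centre node) and the
    # footplate centre node on the lateral surface (stapes output)
    inc_nodes = incus.nodes
    tip_face = inc_nodes[:, 2] >= inc_nodes[:, 2].max() - 1e-12
    centrality = np.linalg.norm(
        inc_nodes[:, :2] - np.asarray(inc["center"][:2]) * MM, axis=1)
    tip_idx = int(np.where(tip_face, centrality, np.inf).argmin())

    fp_nodes = footplate.nodes
    lat_face = fp_nodes[:, 2] <= fp_nodes[:, 2].min() + 1e-12
    out_idx = int(np.where(lat_face, np.linalg.norm(fp_nodes[:, :2], axis=1),
                           np.inf).argmin())

    target_point = fp_nodes[out_idx].copy()

    # footplate SDF grid for drilling
    pad = cfg["sdf"]["padding"] * MM
    spacing = cfg["sdf"]["spacing"] * MM
    lo = np.array([-a - pad, -b - pad, -t_fp / 2 - pad])
    hi = np.array([a + pad, b + pad, t_fp / 2 + pad])
    fp_sdf = primitive_sdf(
        {"kind": "plate", "center": np.zeros(3), "semi_axes": (a, b),
         "half_thickness": t_fp / 2},
        {"bounds": (lo, hi), "spacing": spacing})

    return Scene(
        bodies=bodies,
        springs=springs,
        fixed_nodes=fixed_nodes,
        tools=tools,
        target_point=target_point,
        speculum_diameter=g["speculum_diameter"] * MM,
        named_nodes={"incus_long_process_tip": ("incus", tip_idx),
                     "stapes_output": ("footplate", out_idx)},
        sdf_grids={"footplate": fp_sdf},
        config=cfg,
    )
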