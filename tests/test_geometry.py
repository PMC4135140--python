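"""Synthetic anatomy construction, primitive SDFs, and mesh measures."""

import numpy as np
import pytest
import trimesh

from otosim import build_scene, default_config
from otosim.geometry import (ConfigurationError, ConstructionError, HexMesh,
                             RigidPose, TetMesh, ToolShape, TriShell,
                             analytic_sdf, mesh_volume, primitive_sdf)

MM = 1e-3


class TestBuildScene:
    def test_footplate_lateral_extents(self, scene):
        """Elliptic footplate measures 2.8 x 1.52 mm laterally."""
        fp = scene.bodies["footplate"].mesh.nodes
        assert np.ptp(fp[:, 0]) == pytest.approx(2.8 * MM, rel=1e-9)
        assert np.ptp(fp[:, 1]) == pytest.approx(1.52 * MM, rel=1e-9)

    def test_prosthesis_dimensions(self, scene):
        """Piston prosthesis bounding box is 0.4 mm across by 4.5 mm long."""
        pr = scene.bodies["prosthesis"].mesh.nodes
        assert np.ptp(pr[:, 0]) == pytest.approx(0.4 * MM)
        assert np.ptp(pr[:, 1]) == pytest.approx(0.4 * MM)
        assert np.ptp(pr[:, 2]) == pytest.approx(4.5 * MM)

    def test_all_element_measures_positive(self, scene):
        for body in scene.bodies.values():
            mesh = body.mesh
            if isinstance(mesh, TetMesh):
                assert np.all(mesh.volumes > 0)
            elif isinstance(mesh, HexMesh):
                assert np.all(mesh.volumes > 0)
            elif isinstance(mesh, TriShell):
                assert np.all(mesh.areas > 0)

    def test_target_point_on_footplate_surface(self, scene):
        fp = scene.bodies["footplate"].mesh.nodes
        assert np.any(np.all(np.isclose(fp, scene.target_point), axis=1))

    def test_deterministic_given_config(self):
        a = build_scene()
        b = build_scene()
        for name in a.bodies:
            np.testing.assert_array_equal(a.bodies[name].mesh.nodes,
                                          b.bodies[name].mesh.nodes)
        assert len(a.springs) == len(b.springs)

    def test_invalid_dimension_rejected(self):
        with pytest.raises(ConfigurationError):
            build_scene({"geometry": {"footplate": {"thickness": -1.0}}})

    def test_unknown_config_key_named(self):
        with pytest.raises(ConfigurationError, match="no_such_section"):
            build_scene({"no_such_section": {}})

    def test_default_burr_and_speculum(self, scene):
        assert scene.tools["burr"][0].dims["diameter"] == pytest.approx(
            0.6 * MM)
        assert scene.speculum_diameter == pytest.approx(6.0 * MM)


SHAPES = [
    {"kind": "sphere", "center": np.zeros(3), "radius": 1.0},
    {"kind": "ellipsoid", "center": np.zeros(3),
     "semi_axes": np.array([1.5, 1.0, 0.7])},
    {"kind": "capsule", "a": np.array([0, 0, -1.0]),
     "b": np.array([0, 0, 1.0]), "radius": 0.5},
    {"kind": "cylinder", "center": np.zeros(3), "radius": 1.0,
     "half_height": 0.8},
    {"kind": "box", "center": np.zeros(3),
     "half_extents": np.array([1.0, 0.8, 0.6])},
    {"kind": "plate", "center": np.zeros(3),
     "semi_axes": np.array([1.4, 0.76]), "half_thickness": 0.125},
]


class TestPrimitiveSDF:
    def test_sphere_centre_value(self):
        grid = primitive_sdf({"kind": "sphere", "center": (0, 0, 0),
                              "radius": 0.5},
                             {"bounds": ([-1, -1, -1], [1, 1, 1]),
                              "spacing": 0.05})
        assert grid.sample([[0, 0, 0]])[0] == pytest.approx(-0.5, abs=1e-6)

    def test_sphere_surface_zero_within_half_voxel(self):
        spacing = 0.05
        grid = primitive_sdf({"kind": "sphere", "center": (0, 0, 0),
                              "radius": 0.5},
                             {"bounds": ([-1, -1, -1], [1, 1, 1]),
                              "spacing": spacing})
        theta = np.linspace(0, np.pi, 17)
        pts = 0.5 * np.stack([np.sin(theta), np.zeros_like(theta),
                              np.cos(theta)], axis=1)
        assert np.all(np.abs(grid.sample(pts)) < spacing / 2)

    @pytest.mark.parametrize("shape", SHAPES,
                             ids=[s["kind"] for s in SHAPES])
    def test_negative_inside_at_centroid(self, shape):
        centre = np.atleast_2d(shape.get("center",
                                         (np.asarray(shape.get("a", 0))
                                          + np.asarray(shape.get("b", 0)))
                                         / 2.0))
        assert analytic_sdf(shape, centre)[0] < 0

    @pytest.mark.parametrize("shape", SHAPES,
                             ids=[s["kind"] for s in SHAPES])
    def test_eikonal_gradient_magnitude(self, shape, rng):
        """|grad d| = 1 away from the medial axis (signed distance field)."""
        pts = rng.uniform(-0.6, 0.6, size=(200, 3))
        vals = analytic_sdf(shape, pts)
        # keep points off the medial axis / centre where the gradient kinks
        keep = (vals > -0.45) & (np.linalg.norm(pts, axis=1) > 0.15)
        pts = pts[keep]
        h = 1e-6
        grad = np.zeros_like(pts)
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = h
            grad[:, ax] = (analytic_sdf(shape, pts + e)
                           - analytic_sdf(shape, pts - e)) / (2 * h)
        mags = np.linalg.norm(grad, axis=1)
        near_kink = np.abs(mags - 1.0) > 0.05
        # tolerate isolated samples straddling a gradient discontinuity
        assert near_kink.mean() < 0.05

    def test_unknown_shape_kind(self):
        with pytest.raises(ConfigurationError):
            analytic_sdf({"kind": "torus"}, np.zeros((1, 3)))


class TestMeshVolume:
    def test_unit_cube_hexahedron(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                          [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
                         dtype=float)
        mesh = HexMesh(nodes, np.array([[0, 1, 2, 3, 4, 5, 6, 7]]))
        assert mesh_volume(mesh) == pytest.approx(1.0)

    def test_degenerate_tetrahedron_rejected(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]],
                         dtype=float)
        with pytest.raises(ConstructionError):
            TetMesh(nodes, np.array([[0, 1, 2, 3]]))

    def test_icosphere_volume_against_analytic(self):
        r = 0.7
        ball = trimesh.creation.icosphere(subdivisions=4, radius=r)
        shell = TriShell(np.asarray(ball.vertices),
                         np.asarray(ball.faces), thickness=1.0)
        assert mesh_volume(shell) == pytest.approx(4 / 3 * np.pi * r ** 3,
                                                   rel=0.01)

    def test_additive_over_disjoint_parts(self):
        a = trimesh.creation.icosphere(subdivisions=2, radius=0.5)
        nodes = np.asarray(a.vertices)
        faces = np.asarray(a.faces)
        both = TriShell(np.concatenate([nodes, nodes + 5.0]),
                        np.concatenate([faces, faces + len(nodes)]),
                        thickness=1.0)
        single = TriShell(nodes, faces, thickness=1.0)
        assert mesh_volume(both) == pytest.approx(2 * mesh_volume(single),
                                                  rel=1e-12)

    def test_open_surface_rejected(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        shell = TriShell(nodes, np.array([[0, 1, 2]]), thickness=1.0)
        with pytest.raises(ConstructionError):
            mesh_volume(shell)


class TestToolShape:
    def test_unknown_kind(self):
        with pytest.raises(ConfigurationError):
            ToolShape("laser", {"diameter": 1.0})

    def test_nonpositive_dimension(self):
        with pytest.raises(ConfigurationError):
            ToolShape("sphere_burr", {"diameter": 0.0})

    def test_burr_sdf_is_sphere(self):
        tool = ToolShape("sphere_burr", {"diameter": 0.6 * MM})
        pose = RigidPose(np.array([1.0, 2.0, 3.0]) * MM)
        pts = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.5]]) * MM
        np.testing.assert_allclose(tool.sdf(pts, pose),
                                   [-0.3 * MM, 0.2 * MM], atol=1e-12)

    def test_config_knows_only_known_keys(self):
        cfg = default_config()
        assert cfg["solver"]["time_step"] == 0.04
        assert cfg["tools"]["burr"]["diameter"] == 0.6
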