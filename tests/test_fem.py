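"""Element stiffness oracles, assembly, Rayleigh damping and the implicit
integrator."""

import numpy as np
import pytest
import scipy.sparse as sp

from otosim import build_scene, fem
from otosim.fem import (MechState, SolverSettings, SystemMatrices,
                        assemble_system, backward_euler_step,
                        cst_membrane_stiffness, harmonic_response,
                        rayleigh_damping, tet_element_stiffness)


def oracle_tet_stiffness(coords, young, poisson):
    """Independent B-matrix construction from the coefficient form of the
    linear tetrahedron shape functions (inverse of the [1 x y z] moment
    matrix), kept deliberately separate from the implementation."""
    coords = np.asarray(coords, float)
    A = np.hstack([np.ones((4, 1)), coords])
    vol = abs(np.linalg.det(A)) / 6.0
    Ainv = np.linalg.inv(A)          # rows: coefficients a_i, b_i, c_i, d_i
    B = np.zeros((6, 12))
    for i in range(4):
        b, c, d = Ainv[1, i], Ainv[2, i], Ainv[3, i]
        col = 3 * i
        B[0, col] = b
        B[1, col + 1] = c
        B[2, col + 2] = d
        B[3, col], B[3, col + 1] = c, b
        B[4, col + 1], B[4, col + 2] = d, c
        B[5, col], B[5, col + 2] = d, b
    lam = young * poisson / ((1 + poisson) * (1 - 2 * poisson))
    mu = young / (2 * (1 + poisson))
    D = np.diag([2 * mu] * 3 + [mu] * 3).astype(float)
    D[:3, :3] += lam
    return vol * B.T @ D @ B


class TestTetElement:
    COORDS = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
                       [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)]])

    def test_matches_independent_b_matrix_oracle(self):
        K = tet_element_stiffness(self.COORDS, 1.0, 0.3)
        K_oracle = oracle_tet_stiffness(self.COORDS, 1.0, 0.3)
        np.testing.assert_allclose(K, K_oracle, atol=1e-10)

    def test_rigid_translation_nullspace(self, rng):
        coords = self.COORDS + rng.normal(0, 0.05, (4, 3))
        K = tet_element_stiffness(coords, 2.0e9, 0.3)
        for axis in np.eye(3):
            u = np.tile(axis, 4)
            assert np.abs(K @ u).max() < 1e-6 * np.abs(K).max()

    def test_symmetry(self):
        K = tet_element_stiffness(self.COORDS, 14.1e9, 0.3)
        np.testing.assert_allclose(K, K.T, rtol=0, atol=1e-16 * K.max())

    def test_exactly_six_zero_modes(self):
        K = tet_element_stiffness(self.COORDS, 1.0, 0.3)
        w = np.linalg.eigvalsh(K)
        assert np.sum(w < 1e-8 * w.max()) == 6

    def test_inverted_element_rejected(self):
        coords = self.COORDS.copy()
        coords[[0, 1]] = coords[[1, 0]]
        with pytest.raises(fem.FemError):
            tet_element_stiffness(coords, 1.0, 0.3)


class TestCstElement:
    TRI = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)

    def test_rigid_translation_nullspace(self):
        K = cst_membrane_stiffness(self.TRI, 1.0, 0.3, 0.1)
        for axis in np.eye(3):
            u = np.tile(axis, 3)
            assert np.abs(K @ u).max() < 1e-12

    def test_thickness_scales_linearly(self):
        K1 = cst_membrane_stiffness(self.TRI, 1.0, 0.3, 0.1)
        K2 = cst_membrane_stiffness(self.TRI, 1.0, 0.3, 0.2)
        np.testing.assert_allclose(K2, 2 * K1, atol=1e-14)

    def test_uniaxial_stretch_plane_stress_closed_form(self):
        """Unit right triangle under u_x = x: nodal forces from the hand
        plane-stress solution (sigma_x = E/(1-nu^2), sigma_y = nu sigma_x)."""
        E, nu, t = 1.0, 0.3, 1.0
        K = cst_membrane_stiffness(self.TRI, E, nu, t)
        u = np.zeros(9)
        u[3] = 1.0       # node 2 moves +x by its x-coordinate
        f = K @ u
        sx = E / (1 - nu ** 2)
        sy = nu * sx
        expected = np.array([-sx / 2, -sy / 2, 0,
                             sx / 2, 0, 0,
                             0, sy / 2, 0])
        np.testing.assert_allclose(f, expected, atol=1e-10)

    def test_three_in_plane_zero_modes(self):
        K = cst_membrane_stiffness(self.TRI, 1.0, 0.3, 0.1)
        in_plane = np.ix_([0, 1, 3, 4, 6, 7], [0, 1, 3, 4, 6, 7])
        w = np.linalg.eigvalsh(K[in_plane])
        assert np.sum(w < 1e-8 * w.max()) == 3

    def test_zero_area_rejected(self):
        tri = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(fem.FemError):
            cst_membrane_stiffness(tri, 1.0, 0.3, 0.1)


class TestRayleighDamping:
    def test_paper_parameters(self):
        K = sp.random(8, 8, density=0.5, random_state=0)
        K = (K + K.T).tocsr()
        M = np.ones(8)
        C = rayleigh_damping(M, K, 0.0, 1.0e-4)
        np.testing.assert_allclose(C.toarray(), 1.0e-4 * K.toarray())

    def test_undamped_and_mass_proportional_limits(self):
        K = sp.eye(4).tocsr() * 3.0
        M = np.full(4, 2.0)
        assert np.abs(rayleigh_damping(M, K, 0.0, 0.0).toarray()).max() == 0
        np.testing.assert_allclose(
            rayleigh_damping(M, K, 1.0, 0.0).toarray(), np.diag(M))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            rayleigh_damping(np.ones(3), sp.eye(4).tocsr(), 1.0, 1.0)


class TestAssembly:
    def test_fully_fixed_tet_yields_empty_free_system(self):
        from otosim.geometry import Body, Material, Scene, SpringSet, TetMesh
        mesh = TetMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                                 [0, 0, 1.0]]), np.array([[0, 1, 2, 3]]))
        scene = Scene(bodies={"b": Body("b", mesh, Material(1e9, 0.3, 1e3))},
                      springs=SpringSet(), fixed_nodes={"b": np.arange(4)},
                      tools={}, target_point=np.zeros(3))
        sys = assemble_system(scene)
        assert sys.free.sum() == 0

    def test_spring_block_matches_textbook(self):
        """Adding one spring changes K by exactly k d d^T on its blocks."""
        from otosim.geometry import (Body, Material, Scene, Spring,
                                     SpringSet, TetMesh)
        mesh = TetMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                                 [0, 0, 1.0]]), np.array([[0, 1, 2, 3]]))
        mat = Material(1e6, 0.3, 1e3)
        base = Scene(bodies={"b": Body("b", mesh, mat)}, springs=SpringSet(),
                     fixed_nodes={}, tools={}, target_point=np.zeros(3))
        k, d = 123.0, np.array([1.0, 0, 0])
        sprung = Scene(bodies={"b": Body("b", mesh, mat)},
                       springs=SpringSet([Spring(("b", 0), ("b", 1), k,
                                                 1.0, direction=d)]),
                       fixed_nodes={}, tools={}, target_point=np.zeros(3))
        dK = (assemble_system(sprung).K - assemble_system(base).K).toarray()
        block = k * np.outer(d, d)
        np.testing.assert_allclose(dK[:3, :3], block, atol=1e-12)
        np.testing.assert_allclose(dK[:3, 3:6], -block, atol=1e-12)
        np.testing.assert_allclose(dK[3:6, 3:6], block, atol=1e-12)

    def test_total_lumped_mass_conserved(self, scene):
        from otosim.geometry import HexMesh, TetMesh, TriShell
        sys = assemble_system(scene)
        total = sys.M.sum() / 3.0     # each node mass counted per axis
        expected = 0.0
        for body in scene.bodies.values():
            m = body.mesh
            rho = body.material.density
            if isinstance(m, (TetMesh, HexMesh)):
                expected += rho * np.sum(m.volumes)
            elif isinstance(m, TriShell):
                expected += rho * m.thickness * np.sum(m.areas)
        assert total == pytest.approx(expected, rel=1e-12)

    def test_global_rigid_translation_in_stiffness_nullspace(self):
        """K times a rigid translation vanishes for a spring-free body."""
        from otosim.geometry import Body, Material, Scene, SpringSet
        from otosim.geometry import box_tet_mesh
        mesh = box_tet_mesh(np.zeros(3), [1, 1, 1], [2, 2, 2])
        scene = Scene(bodies={"b": Body("b", mesh, Material(1e9, 0.3, 1e3))},
                      springs=SpringSet(), fixed_nodes={}, tools={},
                      target_point=np.zeros(3))
        sys = assemble_system(scene)
        u = np.tile([1.0, 0, 0], len(mesh.nodes))
        assert np.abs(sys.K @ u).max() < 1e-6 * np.abs(sys.K.data).max()


def one_dof_system(m, k, c_alpha=0.0, c_beta=0.0, x0=0.0):
    K = sp.csr_matrix(np.array([[k]]))
    M = np.array([m])
    C = rayleigh_damping(M, K, c_alpha, c_beta)
    return SystemMatrices(M=M, K=K, C=C, free=np.array([True]),
                          x0=np.array([x0]), node_offsets={}, node_counts={})


class TestBackwardEuler:
    def test_equilibrium_is_fixed_point(self):
        sys = one_dof_system(2.0, 50.0)
        state = MechState(np.array([0.0]), np.array([0.0]))
        out = backward_euler_step(state, sys,
                                  settings=SolverSettings(time_step=0.04))
        assert abs(out.velocities[0]) < 1e-12
        assert abs(out.positions[0]) < 1e-12

    def test_matches_scalar_closed_form(self):
        """One step equals the hand-solved 1-dof backward-Euler update."""
        m, k, beta, dt, f = 2.0, 50.0, 1e-4, 0.04, 1.3
        x, v = 0.01, -0.2
        sys = one_dof_system(m, k, c_beta=beta)
        state = MechState(np.array([x]), np.array([v]))
        out = backward_euler_step(state, sys, np.array([f]),
                                  settings=SolverSettings(time_step=dt))
        # hand solution of m(v+ - v) = dt (f - k x+ - c v+), x+ = x + dt v+
        c = beta * k
        v_plus = (m * v + dt * (f - k * x)) / (m + dt * c + dt * dt * k)
        x_plus = x + dt * v_plus
        assert out.velocities[0] == pytest.approx(v_plus, abs=1e-12)
        assert out.positions[0] == pytest.approx(x_plus, abs=1e-12)

    def test_damped_vibration_dissipates_energy(self):
        m, k = 1.0e-6, 100.0
        sys = one_dof_system(m, k, c_beta=1e-4)
        state = MechState(np.array([1e-3]), np.array([0.0]))
        settings = SolverSettings(time_step=0.04)
        prev = 0.5 * k * state.positions[0] ** 2
        for _ in range(100):
            state = backward_euler_step(state, sys, settings=settings)
            e = (0.5 * m * state.velocities[0] ** 2
                 + 0.5 * k * state.positions[0] ** 2)
            assert e <= prev * (1 + 1e-12)
            prev = e

    @pytest.mark.parametrize("dt", [1e-3, 0.04, 0.5])
    def test_undamped_oscillator_never_grows(self, dt):
        m, k = 1.0, 100.0
        sys = one_dof_system(m, k)
        state = MechState(np.array([1.0]), np.array([0.0]))
        settings = SolverSettings(time_step=dt)
        prev = 0.5 * k
        for _ in range(50):
            state = backward_euler_step(state, sys, settings=settings)
            e = (0.5 * m * state.velocities[0] ** 2
                 + 0.5 * k * state.positions[0] ** 2)
            assert e <= prev * (1 + 1e-12)
            prev = e

    def test_corotational_reduces_to_linear_for_small_displacement(self, rng):
        from otosim.geometry import Body, Material, Scene, SpringSet
        from otosim.geometry import box_tet_mesh
        mesh = box_tet_mesh(np.zeros(3), [1, 1, 1], [1, 1, 1])
        scene = Scene(bodies={"b": Body("b", mesh, Material(1e6, 0.3, 1e3))},
                      springs=SpringSet(), fixed_nodes={}, tools={},
                      target_point=np.zeros(3))
        sys = assemble_system(scene)
        direction = rng.normal(size=sys.ndof)
        direction /= np.linalg.norm(direction)
        ratios = []
        for eps in (1e-3, 1e-5, 1e-7):
            x = sys.x0 + eps * direction
            f_lin = sys.elastic_force(x, corotational=False)
            f_cor = sys.elastic_force(x, corotational=True)
            ratios.append(np.linalg.norm(f_cor - f_lin)
                          / max(np.linalg.norm(f_lin), 1e-300))
        assert ratios[0] > ratios[1] > ratios[2]
        assert ratios[2] < 1e-5


class TestHarmonicResponse:
    def test_one_dof_oracle(self):
        m, k, c = 2.0, 300.0, 0.7
        K = sp.csr_matrix(np.array([[k]]))
        C = sp.csr_matrix(np.array([[c]]))
        omegas = np.array([0.0, 5.0, np.sqrt(k / m), 50.0])
        u = harmonic_response(np.array([m]), K, C, np.array([1.0]), omegas)
        expected = 1.0 / np.abs(k - omegas ** 2 * m + 1j * omegas * c)
        np.testing.assert_allclose(np.abs(u[:, 0]), expected, rtol=1e-8)
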