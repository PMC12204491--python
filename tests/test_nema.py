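"""Inverse membrane equilibrium: element frames, assembly, solves, summaries."""

import numpy as np
import pytest

from aawall.mesh_builder import SurfaceMesh
from aawall.nema_solver import (BiomechParams, MembraneProblem, StressField,
                                assemble_residual, assemble_system,
                                biomech_params, element_distance_to_nodes,
                                element_frame, pressure_to_stress_units,
                                solve_membrane_stress)
from aawall.synthetic_data import make_cylinder_mesh, make_sphere_mesh

P_REF = 93.3   # mmHg
H_REF = 1.5    # mm


def flat_plate(nx=10, ny=8):
    xs, ys = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)])
    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            faces += [(a, a + 1, a + nx + 1), (a, a + nx + 1, a + nx)]
    return SurfaceMesh(verts, np.array(faces))


def uniform_tension_dofs(mesh, problem, T):
    """Nodal dofs representing a constant Cartesian stress tensor T."""
    _, _, meta = assemble_system(problem)
    e1, e2 = meta["e1"], meta["e2"]
    s = np.zeros(3 * mesh.n_vertices)
    for v in range(mesh.n_vertices):
        s[3 * v + 0] = e1[v] @ T @ e1[v]
        s[3 * v + 1] = e2[v] @ T @ e2[v]
        s[3 * v + 2] = e1[v] @ T @ e2[v]
    return s


class TestElementFrame:
    def test_identity_reference_triangle(self):
        f = element_frame(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]))
        assert np.allclose(f.g1, [1, 0, 0])
        assert np.allclose(f.g2, [0, 1, 0])
        assert f.g_det == pytest.approx(1.0)
        assert np.allclose(f.normal, [0, 0, 1])

    def test_metric_determinant_scales_as_s4(self):
        tri = np.array([[0.0, 0, 0], [2, 1, 0], [0.5, 3, 1]])
        f1 = element_frame(tri)
        f2 = element_frame(3.0 * tri)
        assert f2.g_det == pytest.approx(3.0 ** 4 * f1.g_det)

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        tri = np.array([[0.0, 0, 0], [2, 1, 0], [0.5, 3, 1]])
        R = Rotation.from_euler("xyz", [30, -40, 75], degrees=True).as_matrix()
        assert element_frame(tri @ R.T).g_det == pytest.approx(
            element_frame(tri).g_det)

    def test_dual_basis_duality(self):
        f = element_frame(np.array([[0.0, 0, 0], [2, 1, 0], [0.5, 3, 1]]))
        d1, d2 = f.dual_basis
        assert d1 @ f.g1 == pytest.approx(1.0)
        assert d1 @ f.g2 == pytest.approx(0.0, abs=1e-12)
        assert d2 @ f.g2 == pytest.approx(1.0)

    def test_degenerate_triangle_raises(self):
        with pytest.raises(ValueError):
            element_frame(np.array([[0.0, 0, 0], [1, 1, 1], [2, 2, 2]]))


class TestPressureConversion:
    def test_zero(self):
        assert pressure_to_stress_units(0.0) == 0.0

    def test_reference_map(self):
        assert pressure_to_stress_units(93.3) == pytest.approx(1.2439, abs=2e-4)

    def test_hypertensive(self):
        assert pressure_to_stress_units(140.0) == pytest.approx(1.8665, abs=2e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pressure_to_stress_units(-1.0)


class TestResidual:
    def test_zero_stress_zero_pressure(self):
        mesh = make_cylinder_mesh(n_circ=16, n_len=4)
        prob = MembraneProblem(mesh, pressure_mmhg=0.0)
        r = assemble_residual(prob, np.zeros(3 * mesh.n_vertices))
        assert np.abs(r).max() == 0.0

    def test_constant_uniaxial_stress_on_flat_plate(self):
        mesh = flat_plate()
        boundary = np.unique(np.concatenate(mesh.boundary_loops()))
        prob = MembraneProblem(mesh, pressure_mmhg=0.0, fixed_nodes=boundary)
        T = np.zeros((3, 3))
        T[0, 0] = 5.0
        s = uniform_tension_dofs(mesh, prob, T)
        r = assemble_residual(prob, s)
        assert np.abs(r).max() < 1e-10 * 5.0

    def test_exact_laplace_field_residual_decays(self):
        rel = []
        for sub in (2, 3, 4):
            mesh = make_sphere_mesh(R=25.0, subdivisions=sub, band=0.6)
            prob = MembraneProblem(mesh)
            A, b, _ = assemble_system(prob)
            c = pressure_to_stress_units(P_REF) * 25.0 / (2 * H_REF)
            s = np.zeros(3 * mesh.n_vertices)
            s[0::3] = c
            s[1::3] = c      # isotropic tension in any tangent frame
            rel.append(np.linalg.norm(A @ s - b) / np.linalg.norm(b))
        assert rel[0] > rel[1] > rel[2]

    def test_dof_length_mismatch_raises(self):
        mesh = make_cylinder_mesh(n_circ=16, n_len=4)
        prob = MembraneProblem(mesh)
        with pytest.raises(ValueError):
            assemble_residual(prob, np.zeros(5))


@pytest.fixture(scope="module")
def cylinder_solution():
    mesh = make_cylinder_mesh(R=10.0, L=100.0, n_circ=48, n_len=40)
    prob = MembraneProblem(mesh)
    return mesh, prob, solve_membrane_stress(prob)


class TestSolve:
    def test_zero_pressure_zero_stress(self):
        mesh = make_cylinder_mesh(n_circ=16, n_len=6)
        fld = solve_membrane_stress(MembraneProblem(mesh, pressure_mmhg=0.0))
        assert np.abs(fld.sigma1).max() < 1e-10
        assert np.abs(fld.sigma2).max() < 1e-10

    def test_sphere_recovers_laplace_law(self):
        mesh = make_sphere_mesh(R=25.0, subdivisions=4, band=0.6)
        prob = MembraneProblem(mesh)
        fld = solve_membrane_stress(prob)
        exact = pressure_to_stress_units(P_REF) * 25.0 / (2 * H_REF)
        interior = element_distance_to_nodes(mesh, prob.fixed_nodes) >= 3
        for s in (fld.sigma1, fld.sigma2):
            assert np.abs(s[interior] - exact).max() / exact < 0.03

    def test_cylinder_recovers_hoop_stress(self, cylinder_solution):
        _, _, fld = cylinder_solution
        exact = pressure_to_stress_units(P_REF) * 10.0 / H_REF
        mid = np.abs(fld.centroids[:, 2] - 50.0) < 10.0
        assert np.abs(fld.sigma1[mid] - exact).max() / exact < 0.03

    def test_sigma1_dominates_sigma2(self, cylinder_solution):
        _, _, fld = cylinder_solution
        assert (fld.sigma1 >= fld.sigma2 - 1e-12).all()

    def test_pressure_linearity(self, cylinder_solution):
        mesh, _, fld = cylinder_solution
        fld2 = solve_membrane_stress(MembraneProblem(mesh,
                                                     pressure_mmhg=2 * P_REF))
        assert np.allclose(fld2.sigma1, 2 * fld.sigma1, rtol=1e-9)

    def test_thickness_inverse_scaling(self, cylinder_solution):
        mesh, _, fld = cylinder_solution
        fldh = solve_membrane_stress(MembraneProblem(mesh,
                                                     thickness_mm=H_REF / 2))
        assert np.allclose(fldh.sigma1, 2 * fld.sigma1, rtol=1e-9)

    def test_rigid_motion_objectivity(self, cylinder_solution):
        from scipy.spatial.transform import Rotation

        mesh, _, fld = cylinder_solution
        R = Rotation.from_euler("xyz", [20, 35, -50], degrees=True).as_matrix()
        moved = SurfaceMesh(mesh.vertices @ R.T + np.array([5.0, -3.0, 11.0]),
                            mesh.triangles, mesh.proximal_ring, mesh.distal_ring)
        fld2 = solve_membrane_stress(MembraneProblem(moved))
        scale = np.abs(fld.sigma1).max()
        assert np.abs(fld2.sigma1 - fld.sigma1).max() / scale < 1e-6
        assert np.abs(fld2.sigma2 - fld.sigma2).max() / scale < 1e-6

    def test_boundary_rings_required(self):
        closed = make_sphere_mesh(R=10.0, subdivisions=2)  # no boundary
        with pytest.raises(ValueError):
            MembraneProblem(closed)

    def test_near_boundary_flagging(self, cylinder_solution):
        mesh, prob, fld = cylinder_solution
        dist = element_distance_to_nodes(mesh, prob.fixed_nodes)
        assert np.array_equal(fld.near_boundary, dist == 0)


class TestBiomechParams:
    def make_field(self, sigma1, areas):
        n = len(sigma1)
        return StressField(sigma_contra=np.zeros((n, 3)),
                           sigma1=np.asarray(sigma1, dtype=float),
                           sigma2=np.zeros(n),
                           areas=np.asarray(areas, dtype=float),
                           near_boundary=np.zeros(n, dtype=bool),
                           centroids=np.zeros((n, 3)))

    def test_uniform_field_all_equal(self):
        fld = self.make_field([2.5] * 10, [1.0] * 10)
        bp = biomech_params(fld)
        assert (bp.peak_wall_stress == bp.p99 == bp.p75 == bp.mean_stress
                == bp.saws == 2.5)

    def test_two_element_hand_case(self):
        fld = self.make_field([1.0, 3.0], [3.0, 1.0])
        bp = biomech_params(fld)
        assert bp.mean_stress == pytest.approx(2.0)
        assert bp.saws == pytest.approx(1.5)
        assert bp.peak_wall_stress == 3.0

    def test_ordering_invariants(self, cylinder_solution):
        _, _, fld = cylinder_solution
        bp = biomech_params(fld)
        assert bp.peak_wall_stress >= bp.p99 >= bp.p75
        assert bp.peak_wall_stress >= bp.mean_stress
        assert bp.peak_wall_stress >= bp.saws

    def test_saws_stable_under_refinement(self):
        vals = []
        for n_len in (20, 40):
            mesh = make_cylinder_mesh(R=10.0, L=100.0, n_circ=32, n_len=n_len)
            fld = solve_membrane_stress(MembraneProblem(mesh))
            vals.append(biomech_params(fld).saws)
        assert vals[1] == pytest.approx(vals[0], rel=0.01)

    def test_area_weighted_percentile_mode(self):
        fld = self.make_field([1.0, 3.0], [3.0, 1.0])
        bp = biomech_params(fld, area_weighted_percentiles=True)
        assert bp.mean_stress == pytest.approx(1.5)

    def test_empty_field_raises(self):
        with pytest.raises(ValueError):
            biomech_params(self.make_field([], []))
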