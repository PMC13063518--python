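"""Joint-gap fields, curvature estimation, and congruency maps."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tmjmech.core import InvalidInputError, TriangleMesh
from tmjmech import surfaces, synthetic


@pytest.fixture(scope="module")
def sphere_patch():
    return synthetic.gen_surface("sphere", {"radius": 10.0, "cap_angle": 0.35}, 0.3)


class TestJointGap:
    def test_parallel_planes(self):
        a, _ = synthetic.gen_surface("plane", {"extent": 6.0}, 0.5)
        b, _ = synthetic.gen_surface("plane", {"extent": 10.0}, 0.5)
        b = TriangleMesh(b.vertices + [0.0, 0.0, 1.25], b.faces)
        gap = surfaces.joint_gap(a, b)
        assert np.allclose(gap.values, 1.25, atol=1e-9)

    def test_coincident_meshes_zero(self):
        a, _ = synthetic.gen_surface("plane", {"extent": 4.0}, 0.5)
        gap = surfaces.joint_gap(a, a)
        assert np.allclose(gap.values, 0.0, atol=1e-12)

    def test_sphere_above_plane_analytic(self):
        plane, _ = synthetic.gen_surface("plane", {"extent": 8.0}, 0.4)
        sph, _ = synthetic.gen_surface("sphere", {"radius": 5.0, "cap_angle": 0.9}, 0.4)
        # flip the cap downward and hover its lowest point 2 mm above the plane
        verts = sph.vertices * [1.0, 1.0, -1.0] + [0.0, 0.0, 7.0]
        sph_down = TriangleMesh(verts, sph.faces[:, ::-1])
        gap = surfaces.joint_gap(plane, sph_down)
        center = np.array([0.0, 0.0, 7.0])
        expected = np.linalg.norm(plane.vertices - center, axis=1) - 5.0
        # chordal sagitta error at this mesh density
        assert np.abs(gap.values - expected).max() < 0.01
        apex = np.argmin(np.linalg.norm(plane.vertices[:, :2], axis=1))
        assert gap.values[apex] == pytest.approx(2.0, abs=0.01)

    def test_point_to_triangle_beats_vertex_distance(self):
        # a single large triangle far from its vertices
        tri = TriangleMesh(np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0.0]]),
                           np.array([[0, 1, 2]]))
        probe = TriangleMesh(np.array([[3.0, 3.0, 1.0], [3.0, 3.0, 2.0],
                                       [3.1, 3.0, 1.0]]), np.array([[0, 1, 2]]))
        gap = surfaces.joint_gap(probe, tri)
        assert gap.values[0] == pytest.approx(1.0, abs=1e-12)  # foot inside face

    def test_bounds(self):
        a, _ = synthetic.gen_surface("plane", {"extent": 4.0}, 0.5)
        b, _ = synthetic.gen_surface("sphere", {"radius": 3.0, "cap_angle": 0.5}, 0.5)
        b = TriangleMesh(b.vertices + [0.0, 0.0, 4.0], b.faces)
        gap = surfaces.joint_gap(a, b)
        corner_span = np.linalg.norm(
            np.max(np.vstack([a.vertices, b.vertices]), 0)
            - np.min(np.vstack([a.vertices, b.vertices]), 0))
        assert np.all(gap.values >= 0)
        assert np.all(gap.values <= corner_span)

    def test_empty_mesh_rejected(self):
        with pytest.raises(InvalidInputError):
            TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))


class TestPrincipalCurvatures:
    def test_plane_zero(self):
        mesh, _ = synthetic.gen_surface("plane", {"extent": 5.0}, 0.4)
        mesh.vertex_normals = np.tile([0.0, 0.0, 1.0], (mesh.n_vertices, 1))
        curv = surfaces.principal_curvatures(mesh)
        interior = np.max(np.abs(mesh.vertices[:, :2]), axis=1) < 1.5
        assert np.nanmax(np.abs(curv.k_max[interior])) < 1e-6
        assert np.nanmax(np.abs(curv.k_min[interior])) < 1e-6

    def test_sphere_positive_tenth(self, sphere_patch):
        mesh, truth = sphere_patch
        curv = surfaces.principal_curvatures(mesh)
        interior = np.linalg.norm(mesh.vertices[:, :2], axis=1) < 10 * 0.25
        ok = interior & np.isfinite(curv.k_max)
        assert np.allclose(curv.k_max[ok], 0.1, rtol=0.05)
        assert np.allclose(curv.k_min[ok], 0.1, rtol=0.05)

    def test_cylinder(self):
        mesh, _ = synthetic.gen_surface("cylinder", {"radius": 5.0, "length": 5.0,
                                                     "arc": 1.0}, 0.3)
        curv = surfaces.principal_curvatures(mesh)
        interior = (np.abs(mesh.vertices[:, 1]) < 1.5) & (np.abs(mesh.vertices[:, 0]) < 1.5)
        ok = interior & np.isfinite(curv.k_max)
        assert np.allclose(curv.k_max[ok], 0.2, rtol=0.05)
        assert np.abs(curv.k_min[ok]).max() < 0.01

    def test_ordering_invariant(self, sphere_patch):
        mesh, _ = sphere_patch
        curv = surfaces.principal_curvatures(mesh)
        ok = np.isfinite(curv.k_max)
        assert np.all(curv.k_max[ok] >= curv.k_min[ok] - 1e-12)


class TestEquivalentCurvatures:
    def test_two_planes(self):
        assert surfaces.equivalent_curvatures(0, 0, 0, 0) == (0.0, 0.0)

    def test_convex_sphere_in_concave_sphere(self):
        # r=10 ball against r=12 socket: residual curvature 1/10 - 1/12
        kmax, kmin = surfaces.equivalent_curvatures(0.1, 0.1, -1 / 12, -1 / 12)
        assert kmax == pytest.approx(1 / 60, abs=1e-9)
        assert kmin == pytest.approx(1 / 60, abs=1e-9)

    def test_sphere_against_cylinder_hand_value(self):
        kmax, kmin = surfaces.equivalent_curvatures(0.1, 0.1, 0.2, 0.0)
        assert (kmax, kmin) == pytest.approx((0.4, 0.0))

    def test_symmetric_under_surface_swap(self, rng):
        for _ in range(20):
            k1 = np.sort(rng.normal(size=2))[::-1]
            k2 = np.sort(rng.normal(size=2))[::-1]
            a = surfaces.equivalent_curvatures(k1[0], k1[1], k2[0], k2[1])
            b = surfaces.equivalent_curvatures(k2[0], k2[1], k1[0], k1[1])
            assert a == pytest.approx(b)

    def test_ordering_violation_rejected(self):
        with pytest.raises(InvalidInputError):
            surfaces.equivalent_curvatures(0.0, 0.1, 0.0, 0.0)

    def test_orientation_aware_reduces_to_printed_at_right_angle(self):
        base = surfaces.equivalent_curvatures(0.3, 0.1, 0.2, -0.1)
        aware = surfaces.equivalent_curvatures(0.3, 0.1, 0.2, -0.1,
                                               relative_angle=np.pi / 2)
        assert aware == pytest.approx(base)


class TestCongruency:
    @pytest.mark.parametrize("ke,expected", [
        ((0.0, 0.0), 0.0),       # perfect surface match
        ((0.3, 0.3), 0.3),
        ((0.4, 0.0), 0.28284),
    ])
    def test_rms_values(self, ke, expected):
        assert surfaces.congruency(*ke) == pytest.approx(expected, abs=1e-5)


class TestCongruencyMap:
    def test_congruent_pair_near_zero(self):
        condyle, fossa, _ = synthetic.gen_condyle_fossa_pair(
            10.0, 10.0, 0.0, 0.0, edge_length=0.4, cap_angle=0.35)
        cmap = surfaces.congruency_map(condyle, fossa)
        interior = np.linalg.norm(condyle.vertices[:, :2], axis=1) < 10 * 0.25
        vals = cmap.values[interior & np.isfinite(cmap.values)]
        # within 10x the curvature estimation error (~0.5% of 0.1/mm)
        assert np.abs(vals).max() < 10 * 0.005 * 0.1 * 10

    def test_sphere_in_larger_socket(self):
        condyle, fossa, _ = synthetic.gen_condyle_fossa_pair(
            10.0, 12.0, 0.0, 0.0, edge_length=0.4, cap_angle=0.4)
        cmap = surfaces.congruency_map(condyle, fossa)
        interior = np.linalg.norm(condyle.vertices[:, :2], axis=1) < 10 * 0.25
        vals = cmap.values[interior & np.isfinite(cmap.values)]
        assert np.median(vals) == pytest.approx(1 / 10 - 1 / 12, rel=0.10)

    def test_plane_vs_plane_zero(self):
        a, _ = synthetic.gen_surface("plane", {"extent": 4.0}, 0.4)
        b, _ = synthetic.gen_surface("plane", {"extent": 6.0}, 0.4)
        a.vertex_normals = np.tile([0.0, 0.0, 1.0], (a.n_vertices, 1))
        bv = TriangleMesh(b.vertices + [0, 0, 0.4], b.faces,
                          vertex_normals=np.tile([0.0, 0.0, -1.0], (b.n_vertices, 1)))
        cmap = surfaces.congruency_map(a, bv)
        ok = np.isfinite(cmap.values)
        assert np.nanmax(np.abs(cmap.values[ok])) < 1e-6

    def test_joint_rigid_motion_invariance(self):
        condyle, fossa, _ = synthetic.gen_condyle_fossa_pair(
            10.0, 12.0, 0.2, 0.0, edge_length=0.5, cap_angle=0.35)
        base = surfaces.congruency_map(condyle, fossa).values
        rot = Rotation.from_rotvec([0.3, -0.2, 0.5]).as_matrix()
        shift = np.array([4.0, -7.0, 2.0])

        def moved(mesh):
            return TriangleMesh(mesh.vertices @ rot.T + shift, mesh.faces,
                                vertex_normals=mesh.vertex_normals @ rot.T)

        transformed = surfaces.congruency_map(moved(condyle), moved(fossa)).values
        ok = np.isfinite(base) & np.isfinite(transformed)
        assert np.allclose(base[ok], transformed[ok], atol=1e-6)


class TestMeshQuality:
    def test_coarse_mesh_warning_flag(self):
        fine, _ = synthetic.gen_surface("plane", {"extent": 4.0}, 0.3)
        coarse, _ = synthetic.gen_surface("plane", {"extent": 8.0}, 1.0)
        assert not fine.coarse_warning
        assert coarse.coarse_warning

    def test_degenerate_face_rejected(self):
        with pytest.raises(InvalidInputError):
            TriangleMesh(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]]),
                         np.array([[0, 1, 2]]))
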