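"""Mesh container, integral operators and their convergence."""
import math

import numpy as np
import pytest

from spinemech.mesh import (TriMesh, build_icosphere, load_mesh,
                            mean_curvature_vector, save_mesh, validate_mesh,
                            OrientationError)

SPHERE_R = 0.4
SPHERE_AREA = 4 * math.pi * SPHERE_R ** 2
SPHERE_VOL = 4 / 3 * math.pi * SPHERE_R ** 3


def unit_cube() -> TriMesh:
    V = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                  [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float)
    F = np.array([[0, 2, 1], [0, 3, 2],          # bottom (z=0, outward -z)
                  [4, 5, 6], [4, 6, 7],          # top
                  [0, 1, 5], [0, 5, 4],          # y=0
                  [1, 2, 6], [1, 6, 5],          # x=1
                  [2, 3, 7], [2, 7, 6],          # y=1
                  [3, 0, 4], [3, 4, 7]])         # x=0
    return TriMesh(V, F)


class TestIcosphere:
    def test_area_and_volume_match_closed_forms(self, icosphere):
        assert icosphere.surface_area() == pytest.approx(SPHERE_AREA, rel=0.01)
        assert icosphere.enclosed_volume() == pytest.approx(SPHERE_VOL,
                                                            rel=0.01)

    def test_median_edge_near_target(self, icosphere):
        med = np.median(icosphere.edge_lengths())
        assert abs(med - 0.03) / 0.03 < 0.25

    @pytest.mark.parametrize("radius,target", [(0.0, 0.03), (-1.0, 0.03),
                                               (0.4, 0.0), (0.4, 0.5)])
    def test_invalid_parameters_raise(self, radius, target):
        with pytest.raises(ValueError):
            build_icosphere(radius, target)

    def test_convergence_is_second_order(self):
        """Halving the edge length shrinks area/volume error >= 3x."""
        errs_a, errs_v = [], []
        for target in (0.12, 0.06, 0.03):
            m = build_icosphere(SPHERE_R, target)
            errs_a.append(abs(m.surface_area() - SPHERE_AREA))
            errs_v.append(abs(m.enclosed_volume() - SPHERE_VOL))
        assert errs_a[0] / errs_a[1] > 3 and errs_a[1] / errs_a[2] > 3
        assert errs_v[0] / errs_v[1] > 3 and errs_v[1] / errs_v[2] > 3


class TestCubeClosedForms:
    def test_cube_area_and_volume(self):
        cube = unit_cube()
        assert cube.surface_area() == pytest.approx(6.0)
        assert cube.enclosed_volume() == pytest.approx(1.0)

    def test_flipped_face_reports_orientation_error(self):
        cube = unit_cube()
        cube.faces[0] = cube.faces[0][::-1]
        with pytest.raises(OrientationError):
            cube.enclosed_volume()


class TestMeanCurvature:
    @pytest.mark.parametrize("radius", [0.2, 0.4])
    def test_sphere_curvature_magnitude(self, radius):
        m = build_icosphere(radius, radius / 13)
        H = np.linalg.norm(m.mean_curvature_vector(), axis=1)
        assert np.allclose(H, 1.0 / radius, rtol=0.05)

    def test_points_inward_on_convex_body(self, icosphere):
        Hn = mean_curvature_vector(icosphere)
        outward = icosphere.vertices  # sphere centred at origin
        assert (np.einsum("ij,ij->i", Hn, outward) <= 0).all()

    def test_flat_region_has_near_zero_curvature(self):
        cube = unit_cube()
        # subdivide the top face once: its centre vertex is flat
        V = np.vstack([cube.vertices, [[0.5, 0.5, 1.0]]])
        F = [f for f in cube.faces if not (set(f) <= {4, 5, 6, 7})]
        c = 8
        F += [[4, 5, c], [5, 6, c], [6, 7, c], [7, 4, c]]
        m = TriMesh(V, np.array(F))
        H = np.linalg.norm(m.mean_curvature_vector(), axis=1)
        assert H[c] < 1e-10


class TestTranslationInvariance:
    def test_operators_are_translation_invariant(self, bumpy_small_mesh):
        rng = np.random.default_rng(3)
        m = bumpy_small_mesh
        shift = rng.standard_normal(3) * 5.0
        m2 = TriMesh(m.vertices + shift, m.faces.copy())
        assert m2.surface_area() == pytest.approx(m.surface_area(), rel=1e-12)
        assert m2.enclosed_volume() == pytest.approx(m.enclosed_volume(),
                                                     rel=1e-9)
        np.testing.assert_allclose(m2.mean_curvature_vector(),
                                   m.mean_curvature_vector(), atol=1e-8)


class TestValidate:
    def test_icosphere_passes_all_checks(self, icosphere):
        rep = validate_mesh(icosphere)
        assert rep.ok and rep.euler_characteristic == 2

    def test_deleted_face_flags_nonmanifold(self, small_sphere):
        m = small_sphere.copy()
        m.faces = m.faces[1:]
        rep = validate_mesh(m)
        assert not rep.is_closed_manifold

    def test_coincident_vertices_reported(self, small_sphere):
        m = small_sphere.copy()
        m.vertices[1] = m.vertices[0]
        rep = validate_mesh(m)
        assert rep.n_duplicate_vertices > 0


class TestIO:
    @pytest.mark.parametrize("ext", ["off", "ply", "obj"])
    def test_roundtrip_preserves_geometry_and_labels(self, tmp_path,
                                                     small_sphere, ext):
        m = small_sphere.copy()
        m.labels[:5] = 1
        path = tmp_path / f"mesh.{ext}"
        save_mesh(m, path)
        back = load_mesh(path)
        np.testing.assert_allclose(back.vertices, m.vertices, atol=1e-5)
        assert back.n_faces == m.n_faces
        assert (back.labels == m.labels).all()
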