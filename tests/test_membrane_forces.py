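"""Membrane energy, analytic gradients and the tension probe."""
import math

import numpy as np
import pytest

from spinemech import _geometry as geom
from spinemech._kernels import membrane_eval
from spinemech.membrane import (membrane_energy, membrane_force,
                                membrane_force_arrays,
                                tension_force_vectors)
from spinemech.mesh import build_icosphere
from spinemech.params import ModelParams

SPHERE_R = 0.4
SPHERE_BEND = 32 * math.pi * 0.18   # total-curvature Helfrich on any sphere


class TestEnergy:
    def test_sphere_energy_terms(self, icosphere, params):
        eb = membrane_energy(icosphere, params)
        assert eb.pressure_term == pytest.approx(
            params.P * 4 / 3 * math.pi * SPHERE_R ** 3, rel=0.02)
        assert eb.tension_term == pytest.approx(
            params.sigma * 4 * math.pi * SPHERE_R ** 2, rel=0.02)
        assert eb.bending_term == pytest.approx(SPHERE_BEND, rel=0.02)
        assert eb.total == pytest.approx(eb.pressure_term + eb.tension_term
                                         + eb.bending_term)

    def test_zero_kappa_zeroes_bending(self, icosphere, params):
        eb = membrane_energy(icosphere, params.with_(kappa=1e-300))
        assert eb.bending_term == pytest.approx(0.0, abs=1e-250)

    def test_tension_term_linear_in_sigma(self, icosphere, params):
        e1 = membrane_energy(icosphere, params)
        e2 = membrane_energy(icosphere, params.with_(sigma=2 * params.sigma))
        assert e2.tension_term == pytest.approx(2 * e1.tension_term)

    @pytest.mark.parametrize("radius", [0.2, 0.4, 0.8])
    def test_sphere_bending_energy_is_radius_independent(self, radius,
                                                         params):
        m = build_icosphere(radius, radius / 13)
        eb = membrane_energy(m, params)
        assert eb.bending_term == pytest.approx(SPHERE_BEND, rel=0.02)


class TestGradient:
    def test_force_matches_finite_differences(self, bumpy_small_mesh, params):
        """F_mem = -dE/dx, checked by central differences per coordinate."""
        m = bumpy_small_mesh
        force = membrane_force(m, params)
        h = 1e-6

        def energy(V):
            vol, area, eb, _ = membrane_eval(V, m.faces, params.P,
                                             params.sigma, params.kappa,
                                             need_grad=False)
            return params.P * vol + params.sigma * area + eb

        scale = np.abs(force).max()
        for vi in range(m.n_vertices):
            for c in range(3):
                Vp = m.vertices.copy(); Vp[vi, c] += h
                Vm = m.vertices.copy(); Vm[vi, c] -= h
                fd = -(energy(Vp) - energy(Vm)) / (2 * h)
                assert abs(fd - force[vi, c]) / scale < 1e-4

    def test_numba_kernel_matches_numpy_reference(self, bumpy_small_mesh,
                                                  params):
        m = bumpy_small_mesh
        vol, area, eb, grad = membrane_eval(m.vertices, m.faces, params.P,
                                            params.sigma, params.kappa)
        assert vol == pytest.approx(geom.enclosed_volume(m.vertices, m.faces))
        assert area == pytest.approx(geom.surface_area(m.vertices, m.faces))
        eb_np, gb = geom.bending_energy_gradient(m.vertices, m.faces,
                                                 params.kappa)
        assert eb == pytest.approx(eb_np)
        ref = (params.P * geom.volume_gradient(m.vertices, m.faces)
               + params.sigma * geom.area_gradient(m.vertices, m.faces) + gb)
        np.testing.assert_allclose(grad, ref, rtol=1e-10, atol=1e-12)

    def test_sphere_force_is_radial(self, icosphere, params):
        force = membrane_force(icosphere, params)
        rhat = icosphere.vertices / np.linalg.norm(icosphere.vertices,
                                                   axis=1, keepdims=True)
        radial = np.einsum("ij,ij->i", force, rhat)
        tangential = force - radial[:, None] * rhat
        assert (np.linalg.norm(tangential, axis=1).max()
                < 0.05 * np.abs(radial).max())

    def test_net_force_vanishes_on_closed_mesh(self, bumpy_small_mesh,
                                               params):
        """Translation invariance: every component sums to the zero vector."""
        m = bumpy_small_mesh
        _, comps = membrane_force_arrays(m.vertices, m.faces, params,
                                         return_components=True)
        for name, f in comps.items():
            total = np.linalg.norm(f.sum(axis=0))
            assert total < 1e-8 * np.linalg.norm(f, axis=1).sum(), name


class TestTensionProbe:
    def test_zero_sigma_gives_zero_force(self, small_sphere):
        vecs = tension_force_vectors(small_sphere.vertices,
                                     small_sphere.faces, 0.0)
        assert np.abs(vecs).max() == 0.0

    def test_probe_norms_uniform_on_sphere(self, icosphere, params):
        vecs = tension_force_vectors(icosphere.vertices, icosphere.faces,
                                     params.sigma)
        norms = np.linalg.norm(vecs, axis=1)
        assert norms.std() / norms.mean() < 0.10

    def test_probe_equals_area_gradient_finite_difference(self,
                                                          bumpy_small_mesh,
                                                          params):
        m = bumpy_small_mesh
        vecs = tension_force_vectors(m.vertices, m.faces, params.sigma)
        h = 1e-6
        vi = 5
        for c in range(3):
            Vp = m.vertices.copy(); Vp[vi, c] += h
            Vm = m.vertices.copy(); Vm[vi, c] -= h
            fd = -params.sigma * (geom.surface_area(Vp, m.faces)
                                  - geom.surface_area(Vm, m.faces)) / (2 * h)
            assert abs(fd - vecs[vi, c]) <= 1e-4 * max(1.0, abs(fd))
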