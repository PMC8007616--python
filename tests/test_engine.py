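"""Integration, constraints, resting shape, tracking and t* detection."""
import numpy as np
import pytest

from spinemech.engine import (NOT_REACHED, ObservableSeries, PsdState,
                              SimulationState, apply_spine_constraints,
                              capture_psd_vertices, detect_t_star,
                              rk4_positions, rk4_step)
from spinemech.membrane import membrane_energy
from spinemech.mesh import LABEL_NECK, LABEL_PSD, build_icosphere
from spinemech.params import ModelParams
from spinemech.tracking import init_tracking


@pytest.fixture()
def constrained_sphere(params):
    m = build_icosphere(params.r_s, params.delta_s)
    return apply_spine_constraints(m, params)


class TestConstraints:
    def test_psd_projected_and_neck_fixed(self, constrained_sphere, params):
        m = constrained_sphere
        psd = m.labels == LABEL_PSD
        assert psd.any() and (m.labels == LABEL_NECK).any()
        assert np.allclose(m.vertices[psd, 2], params.h_psd)
        # the PSD cap edge sits at the tabulated PSD radius
        r = np.hypot(m.vertices[psd, 0], m.vertices[psd, 1])
        assert r.max() <= params.r_psd0 * 1.05

    def test_constrained_vertices_never_move(self, constrained_sphere,
                                             params):
        st = SimulationState(mesh=constrained_sphere.copy(), params=params)
        fixed_before = st.mesh.vertices[st.mesh.fixed_mask].copy()
        for _ in range(5):
            rk4_step(st)
        fixed_after = st.mesh.vertices[st.mesh.fixed_mask]
        b = fixed_before[np.lexsort(fixed_before.T)]
        a = fixed_after[np.lexsort(fixed_after.T)]
        assert a.shape == b.shape and (a == b).all()


class TestRK4:
    def test_zero_zeta_freezes_positions(self, constrained_sphere, params):
        p = params.with_(zeta=1e-300)
        V0 = constrained_sphere.vertices.copy()
        X = rk4_positions(V0, constrained_sphere.faces,
                          constrained_sphere.free_mask, p, None, p.dt, 1)
        assert np.abs(X - V0).max() < 1e-12

    def test_step_halving_shows_fourth_order(self, small_sphere, params):
        """One RK4 step vs two half steps: error ratio ~ 2^4 under dt
        halving (the classical convergence-order check)."""
        m = small_sphere
        free = np.ones(m.n_vertices, dtype=bool)
        errs = []
        for dt in (0.02, 0.01):
            one = rk4_positions(m.vertices, m.faces, free, params, None,
                                dt, 1)
            two = rk4_positions(m.vertices, m.faces, free, params, None,
                                dt, 2)
            errs.append(np.abs(one - two).max())
        assert errs[0] / errs[1] > 8     # >= 2^3 even with roundoff slack

    def test_energy_decreases_under_pure_gradient_flow(self,
                                                       constrained_sphere):
        """With F_actin = 0 and no remeshing the dynamics is a gradient
        flow: the membrane energy is non-increasing."""
        p = ModelParams(dt=1.0 / 32.0)
        st = SimulationState(mesh=constrained_sphere.copy(), params=p)
        E = [membrane_energy(st.mesh, p).total]
        for _ in range(20):
            rk4_step(st, remesh=False)
            E.append(membrane_energy(st.mesh, p).total)
        assert (np.diff(E) <= 1e-9).all()

    def test_determinism_bitwise(self, constrained_sphere, params):
        runs = []
        for _ in range(2):
            st = SimulationState(mesh=constrained_sphere.copy(),
                                 params=params)
            for _ in range(3):
                rk4_step(st)
            runs.append(st.mesh.vertices.copy())
        assert runs[0].shape == runs[1].shape
        assert (runs[0] == runs[1]).all()


class TestRestingShape:
    def test_psd_exactly_at_h_psd(self, resting, params):
        psd = resting.labels == LABEL_PSD
        assert psd.any()
        assert (resting.vertices[psd, 2] == params.h_psd).all()

    def test_resting_volume_below_initial_sphere(self, resting, params):
        """Positive P and sigma shrink the free surface from the sphere."""
        v_sphere = 4 / 3 * np.pi * params.r_s ** 3
        assert 0.02 < resting.enclosed_volume() < v_sphere

    def test_resting_is_near_stationary(self, resting, params):
        """At the minimum the bulk of the surface is at rest: the median
        per-step motion is tiny, and even the PSD-rim crease flutter stays
        well below one edge length per step."""
        m = resting.copy()
        X = rk4_positions(m.vertices, m.faces, m.free_mask, params, None,
                          params.dt, params.n_substeps)
        disp = np.linalg.norm(X - m.vertices, axis=1)[m.free_mask]
        assert np.median(disp) < 1e-4
        assert disp.max() < 0.2 * params.delta_s


class TestTracking:
    def test_probe_spacing_and_binding(self, resting, params):
        probes = init_tracking(resting, params)
        target = 2 * params.delta_s
        # spacing: median edge of the tracking mesh within the remesher band
        Vt = resting.vertices[probes.bound_idx]
        E = np.concatenate([probes.faces[:, [0, 1]], probes.faces[:, [1, 2]],
                            probes.faces[:, [2, 0]]])
        med = np.median(np.linalg.norm(Vt[E[:, 0]] - Vt[E[:, 1]], axis=1))
        assert 0.8 * target * 0.8 < med < 4 / 3 * target * 1.2
        assert probes.n_probes < resting.n_vertices / 2

    def test_binding_distance_below_delta_s(self, resting, params):
        probes = init_tracking(resting, params)
        # bound vertex is the nearest one, so binding distance is zero
        d = np.linalg.norm(probes.last_positions
                           - resting.vertices[probes.bound_idx], axis=1)
        assert d.max() < params.delta_s

    def test_probe_count_deterministic(self, resting, params):
        a = init_tracking(resting, params)
        b = init_tracking(resting, params)
        assert a.n_probes == b.n_probes
        assert (a.bound_idx == b.bound_idx).all()


class TestDetectTStar:
    def _series(self, values):
        s = ObservableSeries()
        for i, v in enumerate(np.atleast_2d(values)):
            s.t.append(i * 1.0)
            s.probe_norms.append(np.asarray(v))
        return s

    def test_constant_series_never_crosses(self):
        s = self._series([[1.0]] * 10)
        assert detect_t_star(s, 0, 2.5) == NOT_REACHED

    def test_linear_ramp_crossing_time(self):
        # 1 pN growing by 0.1 pN/s: 2.5-fold reached at 15 s
        s = self._series([[1.0 + 0.1 * i] for i in range(31)])
        assert detect_t_star(s, 0, 2.5) == pytest.approx(15.0)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            detect_t_star(ObservableSeries(), 0, 2.5)

    def test_fold_must_exceed_one(self):
        with pytest.raises(ValueError):
            detect_t_star(self._series([[1.0]]), 0, 0.5)


class TestObservableIO:
    def _series(self):
        s = ObservableSeries()
        for i in range(3):
            s.t.append(i * 0.125)
            s.volume.append(0.1 + i * 0.01)
            s.area.append(1.0)
            s.psd_area.append(0.07)
            s.e_pressure.append(1.0)
            s.e_tension.append(2.0)
            s.e_bending.append(3.0)
            s.probe_norms.append(np.full(5, 0.5))
        return s

    def test_hdf5_roundtrip_with_snapshot(self, tmp_path, small_sphere):
        import h5py
        s = self._series()
        path = tmp_path / "run.h5"
        s.save_hdf5(path, snapshots={"final": small_sphere})
        with h5py.File(path) as fh:
            np.testing.assert_allclose(fh["series/t"][:], s.t_arr)
            np.testing.assert_allclose(fh["series/probe_norms"][:],
                                       s.norms_arr)
            assert fh["meshes/final/vertices"].shape == \
                small_sphere.vertices.shape

    def test_foci_csv_roundtrip(self, tmp_path):
        from spinemech.actin import FociSet
        foci = FociSet(positions=[[0.1, 0.2, 0.3], [-0.1, 0.0, 0.2]],
                       phi=0.01)
        path = tmp_path / "foci.csv"
        foci.to_csv(path)
        back = FociSet.from_csv(path, phi=0.01)
        np.testing.assert_allclose(back.positions, foci.positions)
        assert back.active


class TestPsdCapture:
    def test_capture_rule_arithmetic(self, params):
        m = build_icosphere(params.r_s, 0.1)
        m.vertices[0] = [0.1, 0.0, 0.3605]
        m.vertices[1] = [0.3, 0.0, 0.36]
        psd = PsdState(radius=0.18, grow_rate=0.0)
        n = capture_psd_vertices(m, psd, params)
        assert n >= 1
        assert m.vertices[0, 2] == params.h_psd      # inside radius + tol
        assert m.labels[0] == LABEL_PSD
        assert m.labels[1] != LABEL_PSD              # outside radius

    def test_zero_rate_keeps_radius(self, params):
        psd = PsdState(radius=params.r_psd0, grow_rate=0.0)
        psd.step(params.dt)
        assert psd.radius == params.r_psd0
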