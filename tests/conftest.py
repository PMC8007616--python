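"""Shared fixtures.

The heavy simulation fixtures (resting shape, LTP runs, stabilization and
exocytosis series) are session-scoped: each is computed once per pytest
session and shared between the unit and acceptance tests.
"""
from __future__ import annotations

import numpy as np
import pytest

from spinemech.engine import find_resting_shape
from spinemech.mesh import build_icosphere
from spinemech.params import ModelParams
from spinemech.scenarios import (EXPANSION_CAP, EXPANSION_GROWTH, OmegaSpec,
                                 make_expanded_state, make_ltp_state,
                                 make_omega_profile, run_exocytosis, run_ltp,
                                 run_stabilization)
from spinemech.stats import volume_crossing


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def icosphere(params):
    return build_icosphere(params.r_s, params.delta_s)


@pytest.fixture(scope="session")
def small_sphere():
    """Coarse sphere for finite-difference and convergence-order tests."""
    return build_icosphere(0.4, 0.12)


@pytest.fixture(scope="session")
def bumpy_small_mesh(small_sphere):
    """Seeded, slightly perturbed coarse sphere (non-symmetric test mesh)."""
    rng = np.random.default_rng(7)
    m = small_sphere.copy()
    m.vertices = m.vertices + 0.004 * rng.standard_normal(m.vertices.shape)
    return m


@pytest.fixture(scope="session")
def resting(params):
    """The relaxed resting spine shape (expensive; shared per session)."""
    return find_resting_shape(params)


@pytest.fixture(scope="session")
def ltp_run(resting, params):
    """Single near-PSD-focus LTP simulation run to the expansion target,
    with tension probes recorded every step. Returns (series, state)."""
    state = make_ltp_state(resting, params, "near_psd")
    v0 = state.mesh.enclosed_volume()
    series = run_ltp(state, EXPANSION_CAP,
                     stop_volume=EXPANSION_GROWTH * v0)
    return series, state


@pytest.fixture(scope="session")
def expanded(ltp_run):
    """Canonical post-LTP expanded spine (actin switched off)."""
    _, state = ltp_run
    out = state.copy()
    out.foci = None
    out.phase = "expanded"
    return out


@pytest.fixture(scope="session")
def ltp_reference(ltp_run):
    """Self-consistent t*, crossing step, probe id and v* of the
    single-focus run."""
    from spinemech.engine import detect_t_star_max_probe
    from spinemech.stats import tension_summary

    series, _ = ltp_run
    t_star, k, p = detect_t_star_max_probe(series, 2.5)
    arr = series.norms_arr
    return {"t_star": t_star, "k": k, "probe": p,
            "v_star": float(series.volume[k]),
            "summary": tension_summary(arr[k]),
            "summary0": tension_summary(arr[0])}


@pytest.fixture(scope="session")
def stabilization_runs(expanded, params):
    """7-minute relaxation with and without the PSD-growth rule."""
    return {
        "free": run_stabilization(expanded, 0.0, 420.0),
        "stabilized": run_stabilization(expanded, params.delta_s / 60,
                                        420.0),
    }


@pytest.fixture(scope="session")
def omega_runs(expanded):
    """Exocytosis series for the three actin modes, 30 s each."""
    out = {}
    for mode in ("no_actin", "tip_focus", "adjacent_focus"):
        st = expanded.copy()
        om = make_omega_profile(st, OmegaSpec())
        out[mode] = (om, run_exocytosis(st, om, mode, duration=30.0),
                     expanded.mesh.enclosed_volume())
    return out


@pytest.fixture(scope="session")
def foci_sweep(resting, params, ltp_reference):
    """Runs with 3/6/11/22 evenly-spread foci and with a middle / near-neck
    focus, each until the spine volume reaches the single-focus v*."""
    from spinemech.stats import tension_summary

    v_ref = ltp_reference["v_star"]
    out = {}
    for tag, mode, n_f in (("f3", "evenly", 3), ("f6", "evenly", 6),
                           ("f11", "evenly", 11), ("f22", "evenly", 22),
                           ("middle", "middle", 1),
                           ("neck", "near_neck", 1)):
        st = make_ltp_state(resting, params, mode, n_f=n_f)
        ser = run_ltp(st, 150.0, stop_volume=v_ref)
        out[tag] = {"t_to_v": volume_crossing(ser, v_ref),
                    "summary": tension_summary(ser.norms_arr[-1])}
    return out
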