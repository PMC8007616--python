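"""Scenario constructors and procedures: LTP expansion, omega-profile
exocytosis, and PSD-growth stabilization.

The LTP scenarios start from the resting shape with one or more actin
polymerization foci; the exocytosis scenarios impose an omega-shaped
invagination (the shape of a fused recycling endosome) on the expanded
spine and evolve it with or without an actin focus; the stabilization
scenario grows the PSD capture radius and irreversibly fixes membrane
captured at the PSD height.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .actin import FociSet, place_foci
from .engine import (NOT_REACHED, ObservableSeries, PsdState,
                     SimulationState, rk4_step, run_steps)
from .membrane import tension_force
from .mesh import LABEL_FREE, LABEL_PROTECT, TriMesh
from .params import ModelParams
from .remesh import isotropic_remesh, rebind_probes
from .tracking import init_tracking


# ---------------------------------------------------------------------------
# LTP expansion
# ---------------------------------------------------------------------------

def make_ltp_state(resting: TriMesh, params: ModelParams, foci_mode: str,
                   n_f: int = 1, points=None, rng=None) -> SimulationState:
    """Simulation state at LTP onset: resting shape + tracking + foci."""
    pos = place_foci(resting, foci_mode, params, n_f=n_f, points=points,
                     rng=rng)
    n0 = resting.n_vertices
    foci = FociSet.from_counts(pos, params.n_fil, n0)
    probes = init_tracking(resting, params)
    return SimulationState(mesh=resting.copy(), params=params, foci=foci,
                           probes=probes, phase=f"ltp_{foci_mode}",
                           n_vertices0=n0)


def run_ltp(state: SimulationState, duration: float,
            stop_volume: float | None = None) -> ObservableSeries:
    """Run the LTP expansion for ``duration`` seconds (optionally stopping
    once the spine volume reaches ``stop_volume``)."""
    n_steps = int(round(duration / state.params.dt))
    stop = None
    if stop_volume is not None:
        stop = lambda st, se: se.volume[-1] >= stop_volume
    return run_steps(state, n_steps, stop_when=stop)


# Post-LTP "expanded shape": the single-focus spine grown to this factor of
# its resting volume (the starting condition for the exocytosis and
# stabilization procedures).
EXPANSION_GROWTH = 2.7
EXPANSION_CAP = 240.0     # s


def make_expanded_state(resting: TriMesh, params: ModelParams,
                        growth: float = EXPANSION_GROWTH,
                        cap: float = EXPANSION_CAP) -> SimulationState:
    """Canonical post-LTP expanded spine: single near-PSD focus, run until
    the volume reaches ``growth`` times resting (or ``cap`` seconds), actin
    then switched off."""
    state = make_ltp_state(resting, params, "near_psd")
    v0 = state.mesh.enclosed_volume()
    run_ltp(state, cap, stop_volume=growth * v0)
    state.foci = None
    state.phase = "expanded"
    return state


def probe_nearest_focus(state: SimulationState) -> int:
    """Id of the tracking point nearest the (first) focus nucleation site."""
    pos = state.probes.positions(state.mesh)
    d = np.linalg.norm(pos - state.foci.positions[0][None, :], axis=1)
    return int(np.argmin(d))


# ---------------------------------------------------------------------------
# omega profile
# ---------------------------------------------------------------------------

@dataclass
class OmegaSpec:
    """Omega-profile construction parameters."""
    diameter: float = 0.125        # bulb diameter, um (physiological 30-300nm)
    pore_diameter: float = 0.03    # pore opening, um (defaults to delta_s)

    def __post_init__(self):
        if not (0.03 <= self.diameter <= 0.3):
            raise ValueError(
                "omega diameter must lie in the physiological 0.03-0.3 um")


@dataclass
class OmegaState:
    """Reference frame of the constructed invagination."""
    apex: np.ndarray               # pre-construction surface point, um
    axis: np.ndarray               # inward unit vector
    diameter: float
    anchor_vertex: int             # current index of the bulb-tip vertex


def max_tension_free_probe(state: SimulationState) -> int:
    """Probe with the highest tension norm, excluding fixed-region probes."""
    pos = state.probes.positions(state.mesh)
    _, norms = tension_force(state.mesh, state.probes, state.params)
    fixed = state.mesh.fixed_mask[state.probes.bound_idx]
    norms = np.where(fixed, -np.inf, norms)
    return int(np.argmax(norms))


def make_omega_profile(state: SimulationState, spec: OmegaSpec,
                       anchor_probe: int | None = None) -> OmegaState:
    """Impose an inward omega-shaped invagination at the max-tension probe.

    The mesh vertex nearest the chosen tracking point is displaced toward
    the spine centre by one bulb diameter; its 1-2-ring is arranged on a
    sphere of the requested diameter, leaving a pore of ``pore_diameter``
    at the original surface; the surroundings are re-isotropized with the
    bulb protected. The spine volume drops by roughly the bulb volume.
    """
    p = state.params
    mesh = state.mesh
    if anchor_probe is None:
        anchor_probe = max_tension_free_probe(state)
    probe_pos = state.probes.positions(mesh)[anchor_probe]
    free_idx = np.flatnonzero(mesh.labels == LABEL_FREE)
    anchor = int(free_idx[np.argmin(
        np.linalg.norm(mesh.vertices[free_idx] - probe_pos, axis=1))])
    if mesh.fixed_mask[anchor]:
        raise ValueError("omega anchor fell inside a fixed region")

    p0 = mesh.vertices[anchor].copy()
    n_out = mesh.vertex_normals()[anchor]
    axis = -n_out / np.linalg.norm(n_out)      # inward
    D = spec.diameter
    R = D / 2.0
    centre = p0 + axis * R

    # collect 1- and 2-ring of the anchor
    rings = [{anchor}]
    nbrs = _vertex_neighbors(mesh.faces, mesh.n_vertices)
    ring1 = set(nbrs[anchor]) - rings[0]
    ring2 = set()
    for v in ring1:
        ring2.update(nbrs[v])
    ring2 -= ring1 | rings[0]

    theta_pore = math.asin(min(1.0, (spec.pore_diameter / 2.0) / R))
    _place_on_bulb(mesh, [anchor], centre, axis, R, math.pi, p0)
    _place_on_bulb(mesh, sorted(ring1), centre, axis, R, 2.2, p0)
    _place_on_bulb(mesh, sorted(ring2), centre, axis, R, theta_pore + 0.35,
                   p0)

    omega_set = {anchor} | ring1 | ring2
    old_labels = {v: mesh.labels[v] for v in omega_set}
    for v in omega_set:
        if mesh.labels[v] == LABEL_FREE:
            mesh.labels[v] = LABEL_PROTECT

    # re-isotropize with bulb protected; allow protected-protected splits so
    # the coarse bulb refines, then project new bulb vertices to the sphere
    for _ in range(2):
        new_mesh, _ = isotropic_remesh(mesh, p.delta_s, iterations=2,
                                       allow_protected_split=True)
        _project_bulb(new_mesh, centre, axis, R, theta_pore)
        mesh = new_mesh
    state.mesh = mesh
    if state.probes is not None:
        rebind_probes(mesh, state.probes)

    # release the bulb for the subsequent evolution (protection is only a
    # construction-time device; a protected tip would survive as a spike
    # after the surrounding profile heals)
    tip = int(np.argmin(np.linalg.norm(
        mesh.vertices - (centre + axis * R)[None, :], axis=1)))
    prot = mesh.labels == LABEL_PROTECT
    mesh.labels[prot] = LABEL_FREE
    return OmegaState(apex=p0, axis=axis, diameter=D, anchor_vertex=tip)


def _vertex_neighbors(F, n):
    nbrs = [[] for _ in range(n)]
    for a, b, c in F:
        nbrs[a].extend((b, c)); nbrs[b].extend((c, a)); nbrs[c].extend((a, b))
    return nbrs


def _place_on_bulb(mesh, verts, centre, axis, R, theta, p0):
    """Place vertices on the bulb sphere at polar angle ``theta`` (0 = pore,
    pi = tip), keeping each vertex's azimuth about the bulb axis."""
    for v in verts:
        rel = mesh.vertices[v] - p0
        t = rel - np.dot(rel, axis) * axis
        tn = np.linalg.norm(t)
        if tn < 1e-9:
            t = _any_perp(axis); tn = 1.0
        t = t / tn
        # theta = 0 points back to the pore (toward the original surface)
        mesh.vertices[v] = centre + R * (math.sin(theta) * t
                                         + math.cos(theta) * (-axis))


def _project_bulb(mesh, centre, axis, R, theta_pore):
    """Snap vertices near the bulb onto the bulb sphere (below the pore)."""
    rel = mesh.vertices - centre[None, :]
    r = np.linalg.norm(rel, axis=1)
    depth = rel @ axis                      # >0 below centre (toward tip)
    near = (r < 1.35 * R) & (mesh.labels == LABEL_PROTECT)
    polar = np.arccos(np.clip(-depth / np.clip(r, 1e-12, None), -1, 1))
    sel = near & (polar > theta_pore + 0.2)
    mesh.vertices[sel] = centre + rel[sel] * (R / r[sel])[:, None]


def _any_perp(a):
    b = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0., 1., 0.])
    v = np.cross(a, b)
    return v / np.linalg.norm(v)


def omega_depth(mesh: TriMesh, omega: OmegaState,
                core_radius: float = 0.06,
                annulus: tuple = (0.07, 0.12)) -> float:
    """Excess inward excursion of the omega region relative to the local
    surface: max depth in a core cylinder around the bulb axis minus the
    median depth in a surrounding annulus, both restricted to a ball of
    twice the bulb diameter around the apex (so the opposite spine wall is
    never mistaken for the invagination). ~0 once the profile has healed."""
    rel = mesh.vertices - omega.apex[None, :]
    near = np.linalg.norm(rel, axis=1) < 2.0 * omega.diameter
    d_ax = rel @ omega.axis
    lat = np.linalg.norm(rel - d_ax[:, None] * omega.axis[None, :], axis=1)
    core = near & (lat < core_radius)
    ann = near & (lat >= annulus[0]) & (lat < annulus[1])
    if not core.any() or not ann.any():
        return 0.0
    return float(d_ax[core].max() - np.median(d_ax[ann]))


def run_exocytosis(state: SimulationState, omega: OmegaState, mode: str,
                   duration: float = 30.0) -> ObservableSeries:
    """Evolve the omega-bearing spine.

    Modes: ``no_actin`` (myosin has pulled F-actin away; F_actin = 0),
    ``tip_focus`` (single focus at the bulb tip), ``adjacent_focus``
    (single focus one bulb diameter lateral to the tip).
    """
    p = state.params
    if mode == "no_actin":
        state.foci = None
    elif mode in ("tip_focus", "adjacent_focus"):
        tip = omega.apex + omega.axis * omega.diameter
        if mode == "adjacent_focus":
            tip = tip + _any_perp(omega.axis) * omega.diameter
        state.foci = FociSet.from_counts(tip[None, :], p.n_fil,
                                         state.n_vertices0)
    else:
        raise ValueError(f"unknown exocytosis mode {mode!r}")
    state.phase = f"exo_{mode}"

    series = ObservableSeries()
    norms = None
    if state.probes is not None:
        _, norms = tension_force(state.mesh, state.probes, p)
    series.record(state, norms=norms,
                  omega_depth=omega_depth(state.mesh, omega))
    n_steps = int(round(duration / p.dt))
    for _ in range(n_steps):
        rk4_step(state)
        norms = None
        if state.probes is not None:
            _, norms = tension_force(state.mesh, state.probes, p)
        series.record(state, norms=norms,
                      omega_depth=omega_depth(state.mesh, omega))
    return series


def omega_shrink_time(series: ObservableSeries, threshold: float) -> float:
    """Elapsed time (from the start of the series) until the omega-depth
    metric first drops below ``threshold``."""
    d = np.asarray(series.extra["omega_depth"])
    t = series.t_arr
    hit = np.nonzero(d < threshold)[0]
    return float(t[hit[0]] - t[0]) if len(hit) else NOT_REACHED


# ---------------------------------------------------------------------------
# stabilization
# ---------------------------------------------------------------------------

def stabilization_step(state: SimulationState) -> None:
    """One reported step of the PSD-growth stabilization phase (the capture
    rule runs inside :func:`spinemech.engine.rk4_step` when ``state.psd``
    is set)."""
    rk4_step(state)


def run_stabilization(expanded: SimulationState, delta_psd: float,
                      duration: float) -> ObservableSeries:
    """Relax an expanded spine (foci off) while the PSD radius grows at
    ``delta_psd`` and membrane near h_PSD is captured; ``delta_psd = 0``
    is the no-stabilization control."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    state = expanded.copy()
    state.foci = None
    state.phase = f"stabilize_{delta_psd:g}"
    state.psd = PsdState(radius=state.params.r_psd0, grow_rate=delta_psd)
    n_steps = int(round(duration / state.params.dt))
    return run_steps(state, n_steps)
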