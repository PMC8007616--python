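"""Membrane energy, its analytic vertex gradient, and the tension probe.

The membrane energy of the closed spine surface is

    E_mem = P * V + sigma * A + 2*kappa * integral((c1+c2)^2 dA)

with pressure difference P, enclosed volume V, surface tension sigma, area A,
bending modulus kappa and principal curvatures c1, c2 (Helfrich bending with
zero spontaneous curvature, written with the total curvature c1+c2; a sphere
of any radius carries bending energy 32*pi*kappa). The membrane force on
vertex k is the exact negative gradient of the discrete energy,
F_mem = -dE_mem/dx_k. Positive P and sigma penalize volume and area growth:
the resting shape is the constrained minimizer and F_mem pulls any
deformation back toward it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _geometry as geom
from ._kernels import HAVE_NUMBA, membrane_eval
from .mesh import TriMesh
from .params import ModelParams


@dataclass(frozen=True)
class EnergyBreakdown:
    pressure_term: float   # P * V, pN um
    tension_term: float    # sigma * A, pN um
    bending_term: float    # 2 kappa sum_v (c1+c2)_v^2 A_v, pN um

    @property
    def total(self) -> float:
        return self.pressure_term + self.tension_term + self.bending_term


def membrane_energy(mesh: TriMesh, params: ModelParams) -> EnergyBreakdown:
    V, F = mesh.vertices, mesh.faces
    if HAVE_NUMBA:
        vol, area, Eb, _ = membrane_eval(V, F, params.P, params.sigma,
                                         params.kappa, need_grad=False)
    else:
        vol = geom.enclosed_volume(V, F)
        area = geom.surface_area(V, F)
        Eb, _ = geom.bending_energy_gradient(V, F, params.kappa,
                                             need_grad=False)
    return EnergyBreakdown(
        pressure_term=params.P * vol,
        tension_term=params.sigma * area,
        bending_term=Eb,
    )


def membrane_force(mesh: TriMesh, params: ModelParams,
                   return_components: bool = False):
    """Per-vertex membrane force -dE_mem/dx (pN).

    Constrained (fixed) vertices are NOT zeroed here; applying constraints is
    the integrator's job.
    """
    out = membrane_force_arrays(mesh.vertices, mesh.faces, params,
                                return_components=return_components)
    return out


def membrane_force_arrays(V: np.ndarray, F: np.ndarray, params: ModelParams,
                          return_components: bool = False):
    if HAVE_NUMBA and not return_components:
        _, _, _, grad = membrane_eval(V, F, params.P, params.sigma,
                                      params.kappa)
        total = -grad
        if not np.isfinite(total).all():
            bad = int(np.argwhere(~np.isfinite(total).all(axis=1))[0, 0])
            raise FloatingPointError(
                f"non-finite membrane force at vertex {bad}")
        return total
    f_press = -params.P * geom.volume_gradient(V, F)
    f_tens = -params.sigma * geom.area_gradient(V, F)
    _, gb = geom.bending_energy_gradient(V, F, params.kappa)
    f_bend = -gb
    total = f_press + f_tens + f_bend
    if not np.isfinite(total).all():
        bad = int(np.argwhere(~np.isfinite(total).all(axis=1))[0, 0])
        raise FloatingPointError(
            f"non-finite membrane force at vertex {bad}")
    if return_components:
        return total, {"pressure": f_press, "tension": f_tens,
                       "bending": f_bend}
    return total


def tension_force_vectors(V: np.ndarray, F: np.ndarray,
                          sigma: float) -> np.ndarray:
    """sigma-weighted area-gradient vector at every vertex of a probe mesh.

    This is the force generated by membrane tension at a probe point,
    -d(sigma * total area)/dx_j; its norm is the quantity reported in all
    tension histograms and traces.
    """
    return -sigma * geom.area_gradient(V, F)


def tension_force(mesh_or_V, probes, params: ModelParams):
    """Tension-force vectors and norms at Lagrangian probe points.

    ``probes`` is a :class:`spinemech.tracking.TrackingSet` bound to ``mesh``;
    the gradient is taken on the probes' own coarse tracking mesh (the
    membrane sampled at 2*delta_s), which makes the summed norms a
    resolution-independent proxy for sigma * integral 2|H| dA.
    """
    Vt = probes.positions(mesh_or_V)
    vecs = tension_force_vectors(Vt, probes.faces, params.sigma)
    return vecs, np.linalg.norm(vecs, axis=1)
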