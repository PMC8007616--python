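"""Lagrangian tension probes.

The tracking points are the vertices of a coarse isotropic mesh (edge length
2*delta_s) built once on the resting shape. Each probe is bound to the
nearest vertex of the fine simulation mesh and rides on it; after every
remesh the probes rebind to the nearest surviving vertex. The tension force
at a probe is the sigma-weighted area gradient of the coarse tracking mesh
evaluated at the current probe positions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TriMesh
from .params import ModelParams


@dataclass
class TrackingSet:
    faces: np.ndarray                # (mt, 3) fixed connectivity of probes
    bound_idx: np.ndarray            # (nt,) fine-mesh vertex per probe
    last_positions: np.ndarray       # (nt, 3) cached probe positions

    @property
    def n_probes(self) -> int:
        return len(self.bound_idx)

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.n_probes)

    def positions(self, mesh_or_V) -> np.ndarray:
        V = mesh_or_V.vertices if isinstance(mesh_or_V, TriMesh) else mesh_or_V
        pos = V[self.bound_idx]
        self.last_positions = pos.copy()
        return pos


def init_tracking(resting: TriMesh, params: ModelParams) -> TrackingSet:
    """Probe set: vertices of a 2*delta_s isotropic remesh of the resting
    shape, each bound to its nearest resting-mesh vertex. Deterministic."""
    from .remesh import isotropic_remesh

    coarse, _ = isotropic_remesh(resting.copy(), 2.0 * params.delta_s,
                                 iterations=10)
    tree = cKDTree(resting.vertices)
    _, idx = tree.query(coarse.vertices)
    return TrackingSet(faces=coarse.faces.copy(),
                       bound_idx=idx.astype(np.int64),
                       last_positions=resting.vertices[idx].copy())
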