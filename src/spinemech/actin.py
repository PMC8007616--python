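"""Continuous F-actin polymerization force and focus placement.

A polymerization focus is a point f_i inside the spine from which filament
barbed ends push the membrane outward. The force on membrane vertex x_k is

    F_actin(f_i, x_k) = alpha * phi(n_f) / d(f_i, x_k) * unit(x_k - f_i)

summed over all active foci. The 1/d decay encodes G-actin depletion as the
spine expands (the protrusion slows as it grows); phi = n_fil/(n_vertices0 *
n_f) shares a fixed total filament budget among foci and makes the total
applied force independent of mesh resolution and focus count.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TriMesh
from .params import ModelParams


def phi_factor(n_fil: int, n_vertices0: int, n_f: int) -> float:
    """Force-sharing factor phi(n_f) = n_fil / (n_vertices0 * n_f)."""
    if n_fil <= 0 or n_vertices0 <= 0 or n_f <= 0:
        raise ValueError("n_fil, n_vertices0 and n_f must be positive")
    return n_fil / (n_vertices0 * n_f)


@dataclass
class FociSet:
    """Static nucleation positions of the polymerization foci."""

    positions: np.ndarray          # (n_f, 3), um
    phi: float                     # dimensionless sharing factor
    active: bool = True

    def __post_init__(self):
        self.positions = np.atleast_2d(
            np.asarray(self.positions, dtype=np.float64))

    @property
    def n_f(self) -> int:
        return len(self.positions)

    @classmethod
    def from_counts(cls, positions, n_fil: int, n_vertices0: int) -> "FociSet":
        positions = np.atleast_2d(np.asarray(positions, dtype=np.float64))
        return cls(positions,
                   phi_factor(n_fil, n_vertices0, len(positions)))

    def to_csv(self, path) -> None:
        import csv
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "x", "y", "z", "active"])
            for i, p in enumerate(self.positions):
                w.writerow([i, p[0], p[1], p[2], int(self.active)])

    @classmethod
    def from_csv(cls, path, phi: float) -> "FociSet":
        import csv
        with open(path) as fh:
            rows = list(csv.DictReader(fh))
        pos = [[float(r["x"]), float(r["y"]), float(r["z"])] for r in rows]
        active = all(int(r["active"]) for r in rows) if rows else True
        return cls(np.asarray(pos), phi, active=active)


def actin_force_arrays(V: np.ndarray, foci: FociSet | None,
                       params: ModelParams) -> np.ndarray:
    """Per-vertex actin force (pN); zero field for inactive/absent foci."""
    out = np.zeros_like(V)
    if foci is None or not foci.active or foci.n_f == 0:
        return out
    amp = params.alpha * foci.phi
    d_min = params.d_min
    for f in foci.positions:
        dvec = V - f[None, :]
        d = np.linalg.norm(dvec, axis=1)
        d_safe = np.clip(d, 1e-12, None)
        mag = amp / np.clip(d, d_min, None)     # 1/d, clamped below d_min
        out += (mag / d_safe)[:, None] * dvec
    return out


def actin_force(mesh: TriMesh, foci: FociSet, params: ModelParams) -> np.ndarray:
    return actin_force_arrays(mesh.vertices, foci, params)


# ---------------------------------------------------------------------------
# focus placement on the resting shape
# ---------------------------------------------------------------------------

_SCALE = 0.99   # foci sit at 99% of a resting-shape vertex position


def _psd_rim_distance(V: np.ndarray, params: ModelParams) -> np.ndarray:
    """Distance from each vertex to the PSD rim circle."""
    r = np.linalg.norm(V[:, :2], axis=1)
    return np.hypot(r - params.r_psd0, V[:, 2] - params.h_psd)


def place_foci(resting: TriMesh, mode: str, params: ModelParams,
               n_f: int = 1, points=None, rng=None) -> np.ndarray:
    """Focus nucleation positions for a scenario (positions only).

    Modes: ``near_psd`` / ``middle`` / ``near_neck`` pick a single
    resting-shape vertex (nearest the PSD rim, the head equator, or the top
    of the neck) scaled by 0.99 toward the origin. ``evenly`` coarsens the
    0.99-scaled resting shape and spreads ``n_f`` foci over the head.
    ``explicit`` passes ``points`` through. ``random_head`` (robustness
    configs) samples head vertices with an explicit ``rng``.
    """
    V = resting.vertices
    head_z = params.h_neck + params.r_neck
    if mode == "explicit":
        return np.atleast_2d(np.asarray(points, dtype=np.float64))
    if mode == "near_psd":
        idx = int(np.argmin(_psd_rim_distance(V, params)))
        return _SCALE * V[[idx]]
    if mode == "middle":
        z_mid = 0.5 * (params.h_psd + params.h_neck)
        free = np.flatnonzero(resting.free_mask)
        idx = free[int(np.argmin(np.abs(V[free, 2] - z_mid)))]
        return _SCALE * V[[idx]]
    if mode == "near_neck":
        free = np.flatnonzero(resting.free_mask)
        idx = free[int(np.argmin(np.abs(V[free, 2] - head_z)))]
        return _SCALE * V[[idx]]
    if mode == "random_head":
        if rng is None:
            raise ValueError("random_head placement needs an explicit rng")
        head = np.flatnonzero(V[:, 2] > head_z)
        idx = rng.choice(head, size=n_f, replace=False)
        return _SCALE * V[idx]
    if mode == "evenly":
        return _evenly_spread(resting, params, n_f)
    raise ValueError(f"unknown foci placement mode {mode!r}")


def _evenly_spread(resting: TriMesh, params: ModelParams,
                   n_f: int) -> np.ndarray:
    """n_f foci evenly spread over the head of the 0.99-scaled resting shape.

    The scaled shape is remeshed at a coarse target length so its vertex
    density matches the requested count, then exactly ``n_f`` head vertices
    are kept by farthest-point selection seeded at the PSD rim (so the single
    -focus case coincides with the near-PSD scenario).
    """
    from .remesh import isotropic_remesh

    head_z = params.h_neck + params.r_neck
    scaled = TriMesh(_SCALE * resting.vertices.copy(), resting.faces.copy())
    area = scaled.surface_area()
    # coarsen to >= 3*n_f head vertices but never below a resolvable shape
    n_target = max(3 * n_f, 40)
    L = float(np.sqrt(2.0 * area / (np.sqrt(3.0) * n_target)))
    coarse, _ = isotropic_remesh(scaled, target_length=L, iterations=10)
    head = np.flatnonzero(coarse.vertices[:, 2] > head_z)
    if len(head) < n_f:
        raise ValueError(
            f"only {len(head)} coarse head vertices available for {n_f} foci")
    P = coarse.vertices[head]
    seed = int(np.argmin(_psd_rim_distance(P / _SCALE, params)))
    chosen = [seed]
    d = np.linalg.norm(P - P[seed], axis=1)
    while len(chosen) < n_f:
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(P - P[nxt], axis=1))
    return P[np.array(chosen)]
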