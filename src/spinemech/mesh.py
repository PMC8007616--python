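"""Triangulated-surface container and the geometric operators on it.

The spine membrane is a closed orientable triangle mesh. Vertices carry a
small integer label: 0 = free, ``LABEL_PSD`` = PSD disc (fixed at z=h_PSD),
``LABEL_NECK`` = neck cap (fixed), ``LABEL_PROTECT`` = free but protected
from remeshing (e.g. the omega-profile anchor). The boolean ``fixed_mask``
derives from the labels.
"""
from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh as _trimesh

from . import _geometry as geom

LABEL_FREE = 0
LABEL_PSD = 1
LABEL_NECK = 2
LABEL_PROTECT = 3


class MeshError(ValueError):
    pass


class OrientationError(MeshError):
    pass


@dataclass
class TriMesh:
    """Closed oriented triangle mesh with per-vertex labels."""

    vertices: np.ndarray              # (n, 3) float64, um
    faces: np.ndarray                 # (m, 3) int64, CCW from outside
    labels: np.ndarray = None         # (n,) uint8

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.labels is None:
            self.labels = np.zeros(len(self.vertices), dtype=np.uint8)
        else:
            self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if len(self.labels) != len(self.vertices):
            raise MeshError("labels must align with vertices")

    # -- basic queries -----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def fixed_mask(self) -> np.ndarray:
        return (self.labels == LABEL_PSD) | (self.labels == LABEL_NECK)

    @property
    def free_mask(self) -> np.ndarray:
        return ~self.fixed_mask

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(),
                       self.labels.copy())

    def edge_lengths(self) -> np.ndarray:
        E = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                            self.faces[:, [2, 0]]])
        key = np.minimum(E[:, 0], E[:, 1]) * self.n_vertices \
            + np.maximum(E[:, 0], E[:, 1])
        _, first = np.unique(key, return_index=True)
        Eu = E[first]
        return np.linalg.norm(self.vertices[Eu[:, 0]] - self.vertices[Eu[:, 1]],
                              axis=1)

    # -- integral quantities -----------------------------------------------
    def surface_area(self) -> float:
        _, areas = geom.face_normals_areas(self.vertices, self.faces)
        if (areas <= 0).any():
            warnings.warn("degenerate (zero-area) faces contribute 0 area")
        return float(areas.sum())

    def enclosed_volume(self) -> float:
        vol = geom.enclosed_volume(self.vertices, self.faces)
        if vol < 0:
            raise OrientationError(
                f"negative enclosed volume {vol:.6g}: inconsistent orientation")
        # a consistently oriented closed mesh has all directed edges unique
        E = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                            self.faces[:, [2, 0]]])
        dkey = E[:, 0].astype(np.int64) * self.n_vertices + E[:, 1]
        if len(np.unique(dkey)) != len(dkey):
            raise OrientationError("inconsistently oriented faces "
                                   "(duplicated directed edge)")
        return vol

    def mean_curvature_vector(self) -> np.ndarray:
        """Per-vertex mean-curvature normal (um^-1), inward on convex bodies."""
        return geom.mean_curvature_normals(self.vertices, self.faces)

    def vertex_normals(self) -> np.ndarray:
        return geom.vertex_normals(self.vertices, self.faces)


def surface_area(mesh: TriMesh) -> float:
    return mesh.surface_area()


def enclosed_volume(mesh: TriMesh) -> float:
    return mesh.enclosed_volume()


def mean_curvature_vector(mesh: TriMesh) -> np.ndarray:
    return mesh.mean_curvature_vector()


def build_icosphere(radius: float, target_edge: float) -> TriMesh:
    """Subdivided icosahedron approximating a sphere centred at the origin.

    The subdivision level is chosen so the median edge length is within 25%
    of ``target_edge``.
    """
    if radius <= 0 or target_edge <= 0:
        raise ValueError("radius and target_edge must be positive")
    if target_edge >= radius:
        raise ValueError("target_edge must be smaller than radius")
    ico_edge = radius / math.sin(2 * math.pi / 5)
    sub = max(1, round(math.log2(ico_edge / target_edge)))
    tm = _trimesh.creation.icosphere(subdivisions=sub, radius=radius)
    return TriMesh(np.array(tm.vertices), np.array(tm.faces))


@dataclass
class MeshReport:
    n_vertices: int
    n_faces: int
    euler_characteristic: int
    is_closed_manifold: bool
    is_oriented: bool
    signed_volume: float
    n_duplicate_vertices: int
    n_degenerate_faces: int
    edge_min: float
    edge_max: float
    edge_median: float
    min_face_quality: float

    @property
    def ok(self) -> bool:
        return (self.is_closed_manifold and self.is_oriented
                and self.n_duplicate_vertices == 0
                and self.n_degenerate_faces == 0 and self.signed_volume > 0)


def validate_mesh(mesh: TriMesh, duplicate_tol: float = 1e-9) -> MeshReport:
    """Diagnostic report: manifoldness, orientation, duplicates, edge stats."""
    V, F = mesh.vertices, mesh.faces
    n = len(V)
    E = np.concatenate([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]])
    key = np.minimum(E[:, 0], E[:, 1]).astype(np.int64) * n \
        + np.maximum(E[:, 0], E[:, 1])
    uniq, counts = np.unique(key, return_counts=True)
    closed = bool((counts == 2).all())
    # orientation: each undirected edge must appear once in each direction
    dkey = E[:, 0].astype(np.int64) * n + E[:, 1]
    oriented = bool(len(np.unique(dkey)) == len(dkey)) and closed

    # duplicates within tolerance (grid hash)
    q = np.round(V / max(duplicate_tol, 1e-12)).astype(np.int64)
    _, dup_counts = np.unique(q, axis=0, return_counts=True)
    n_dup = int((dup_counts > 1).sum())

    _, areas = geom.face_normals_areas(V, F)
    n_degen = int((areas <= 1e-16).sum())

    el = mesh.edge_lengths()
    # quality: 4*sqrt(3)*A / (sum of squared edge lengths); 1 for equilateral
    p = [V[F[:, c]] for c in range(3)]
    L2 = sum(((p[(c + 1) % 3] - p[c]) ** 2).sum(axis=1) for c in range(3))
    qual = 4 * math.sqrt(3) * areas / np.clip(L2, 1e-300, None)

    return MeshReport(
        n_vertices=n, n_faces=len(F),
        euler_characteristic=n - len(uniq) + len(F),
        is_closed_manifold=closed, is_oriented=oriented,
        signed_volume=geom.enclosed_volume(V, F),
        n_duplicate_vertices=n_dup, n_degenerate_faces=n_degen,
        edge_min=float(el.min()), edge_max=float(el.max()),
        edge_median=float(np.median(el)),
        min_face_quality=float(qual.min()),
    )


# -- I/O ---------------------------------------------------------------------

def save_mesh(mesh: TriMesh, path: str | Path) -> None:
    """Write OFF/PLY(ascii)/OBJ (by extension) plus a labels sidecar CSV."""
    path = Path(path)
    tm = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    kwargs = {"encoding": "ascii"} if path.suffix.lower() == ".ply" else {}
    tm.export(path, **kwargs)
    side = path.with_suffix(path.suffix + ".labels.csv")
    with open(side, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vertex_index", "label", "fixed"])
        for i, lab in enumerate(mesh.labels):
            w.writerow([i, int(lab), int(lab in (LABEL_PSD, LABEL_NECK))])


def load_mesh(path: str | Path) -> TriMesh:
    path = Path(path)
    tm = _trimesh.load(path, process=False, force="mesh")
    mesh = TriMesh(np.array(tm.vertices), np.array(tm.faces))
    side = path.with_suffix(path.suffix + ".labels.csv")
    if side.exists():
        with open(side) as fh:
            rows = list(csv.DictReader(fh))
        for row in rows:
            mesh.labels[int(row["vertex_index"])] = int(row["label"])
    return mesh
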