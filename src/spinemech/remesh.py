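"""Incremental isotropic remeshing with protected vertices.

Per iteration the classic split / collapse / flip / tangential-relax loop is
applied: edges longer than 4/3 of the target are split at their midpoint,
edges shorter than 4/5 of the target are collapsed (guarded by the manifold
link condition), edges are flipped when that moves vertex valences toward 6,
and free vertices relax toward their neighbour centroid restricted to the
local tangent plane (so the shape, volume in particular, drifts only at
second order).

Protected vertices (fixed PSD/neck sets, the omega anchor) are never moved,
never collapsed away, and edges between two protected vertices are left
untouched (except during omega construction, where midpoint inheritance is
explicitly requested).

Candidate detection is vectorized; the structural surgery falls back to
index maps only when there is actual work, so a call on an already-isotropic
mesh costs a few milliseconds.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _geometry as geom
from .mesh import TriMesh, MeshError, LABEL_FREE

_SPLIT_FACTOR = 4.0 / 3.0
_COLLAPSE_FACTOR = 4.0 / 5.0


@dataclass
class RemeshReport:
    n_splits: int = 0
    n_collapses: int = 0
    n_flips: int = 0
    edge_median_before: float = 0.0
    edge_median_after: float = 0.0


def _halfedges(F: np.ndarray):
    """Directed halfedge arrays (u, v, opposite, face)."""
    hu = np.concatenate([F[:, 0], F[:, 1], F[:, 2]])
    hv = np.concatenate([F[:, 1], F[:, 2], F[:, 0]])
    ho = np.concatenate([F[:, 2], F[:, 0], F[:, 1]])
    hf = np.tile(np.arange(len(F)), 3)
    return hu, hv, ho, hf


def _unique_edges(F: np.ndarray, n: int):
    hu, hv, _, _ = _halfedges(F)
    key = np.minimum(hu, hv).astype(np.int64) * n + np.maximum(hu, hv)
    uniq, first, counts = np.unique(key, return_index=True,
                                    return_counts=True)
    return np.stack([hu[first], hv[first]], axis=1), counts


def isotropic_remesh(mesh: TriMesh, target_length: float, iterations: int = 3,
                     protected: np.ndarray | None = None,
                     allow_protected_split: bool = False,
                     relax_lambda: float = 1.0):
    """Remesh toward uniform edge length; returns ``(TriMesh, RemeshReport)``.

    ``protected`` defaults to the mesh's non-free labels. The output carries
    labels through all operations; protected vertex positions are bit-exact.
    """
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    V = mesh.vertices.copy()
    F = mesh.faces.copy()
    labels = mesh.labels.copy()
    if protected is None:
        prot = labels != LABEL_FREE
    else:
        prot = np.asarray(protected, dtype=bool).copy()

    report = RemeshReport(edge_median_before=float(
        np.median(mesh.edge_lengths())))

    for _ in range(iterations):
        V, F, labels, prot, ns = _split_pass(
            V, F, labels, prot, _SPLIT_FACTOR * target_length,
            allow_protected_split)
        report.n_splits += ns
        V, F, labels, prot, nc = _collapse_pass(
            V, F, labels, prot, _COLLAPSE_FACTOR * target_length,
            _SPLIT_FACTOR * target_length)
        report.n_collapses += nc
        F, nf = _flip_pass(V, F)
        report.n_flips += nf
        V = _tangential_relax(V, F, prot, relax_lambda)

    V, F, labels = _compact(V, F, labels)
    out = TriMesh(V, F, labels)
    report.edge_median_after = float(np.median(out.edge_lengths()))
    _check_closed(out)
    return out, report


def _check_closed(mesh: TriMesh) -> None:
    _, counts = _unique_edges(mesh.faces, mesh.n_vertices)
    if not (counts == 2).all():
        raise MeshError("remeshing produced a non-manifold mesh")


def _compact(V, F, labels):
    used = np.zeros(len(V), dtype=bool)
    used[F.ravel()] = True
    remap = -np.ones(len(V), dtype=np.int64)
    remap[used] = np.arange(used.sum())
    return (np.ascontiguousarray(V[used]), remap[F],
            np.ascontiguousarray(labels[used]))


# -- split -------------------------------------------------------------------

def _split_pass(V, F, labels, prot, max_len, allow_protected_split,
                max_rounds=12):
    n_splits = 0
    for _ in range(max_rounds):
        n = len(V)
        hu, hv, ho, hf = _halfedges(F)
        up = hu < hv                   # each undirected edge once
        Eu = np.stack([hu[up], hv[up]], axis=1)
        lens = np.linalg.norm(V[Eu[:, 0]] - V[Eu[:, 1]], axis=1)
        long_idx = np.nonzero(lens > max_len)[0]
        if not allow_protected_split and len(long_idx):
            both = prot[Eu[long_idx, 0]] & prot[Eu[long_idx, 1]]
            long_idx = long_idx[~both]
        if len(long_idx) == 0:
            break
        order = long_idx[np.argsort(-lens[long_idx])]
        # directed-edge -> face lookup
        dkey = hu.astype(np.int64) * n + hv
        sk = np.argsort(dkey)
        dkey_s, hf_s = dkey[sk], hf[sk]

        def face_of(x, y):
            return int(hf_s[np.searchsorted(dkey_s, x * n + y)])

        face_dirty = np.zeros(len(F), dtype=bool)
        new_verts, new_labels, new_prot, new_faces = [], [], [], []
        dead = []
        w = n
        for ei in order:
            u, v = int(Eu[ei, 0]), int(Eu[ei, 1])
            f1, f2 = face_of(u, v), face_of(v, u)
            if face_dirty[f1] or face_dirty[f2]:
                continue
            new_verts.append(0.5 * (V[u] + V[v]))
            if prot[u] and prot[v] and labels[u] == labels[v]:
                new_labels.append(labels[u]); new_prot.append(True)
            else:
                new_labels.append(LABEL_FREE); new_prot.append(False)
            for fi in (f1, f2):
                a, b, c = F[fi]
                for _r in range(3):
                    if {a, b} == {u, v}:
                        break
                    a, b, c = b, c, a
                new_faces.append((a, w, c))
                new_faces.append((w, b, c))
            face_dirty[[f1, f2]] = True
            dead.extend((f1, f2))
            w += 1
            n_splits += 1
        if not new_verts:
            break
        V = np.vstack([V, np.array(new_verts)])
        labels = np.concatenate([labels,
                                 np.array(new_labels, dtype=np.uint8)])
        prot = np.concatenate([prot, np.array(new_prot, dtype=bool)])
        F = np.vstack([F[~face_dirty],
                       np.array(new_faces, dtype=np.int64)])
    return V, F, labels, prot, n_splits


# -- collapse ----------------------------------------------------------------

def _collapse_pass(V, F, labels, prot, min_len, max_len, max_rounds=30):
    """Halfedge collapses at the midpoint (or into a protected endpoint).

    Within a round all index maps are static: every collapse marks the full
    one-ring neighbourhood as touched, and touched candidates are deferred
    to the next round, so no incremental connectivity updates are needed.
    """
    n_collapses = 0
    for _ in range(max_rounds):
        n = len(V)
        hu0, hv0, _, _ = _halfedges(F)
        up = hu0 < hv0
        Eu = np.stack([hu0[up], hv0[up]], axis=1)
        lens = np.linalg.norm(V[Eu[:, 0]] - V[Eu[:, 1]], axis=1)
        short = np.nonzero(lens < min_len)[0]
        if len(short):
            both = prot[Eu[short, 0]] & prot[Eu[short, 1]]
            short = short[~both]
        if len(short) == 0:
            break
        order = short[np.argsort(lens[short])]
        su = np.argsort(hu0)
        hu_s, hv_s = hu0[su], hv0[su]
        fv = F.ravel()
        sf = np.argsort(fv, kind="stable")
        fv_s, face_s = fv[sf], sf // 3
        touched = np.zeros(n, dtype=bool)
        face_dead = np.zeros(len(F), dtype=bool)
        remap = np.arange(n)
        count = 0
        for ei in order:
            u, v = int(Eu[ei, 0]), int(Eu[ei, 1])
            if touched[u] or touched[v]:
                continue
            if prot[v]:
                u, v = v, u            # u survives
            lo, hi = np.searchsorted(fv_s, (u, u + 1))
            fu = face_s[lo:hi]
            lo, hi = np.searchsorted(fv_s, (v, v + 1))
            fvv = face_s[lo:hi]
            shared = np.intersect1d(fu, fvv)
            if len(shared) != 2:
                continue
            lo, hi = np.searchsorted(hu_s, (u, u + 1))
            nu = hv_s[lo:hi]
            lo, hi = np.searchsorted(hu_s, (v, v + 1))
            nv = hv_s[lo:hi]
            opp = np.setdiff1d(F[shared].ravel(), (u, v))
            if not np.array_equal(np.intersect1d(nu, nv), np.sort(opp)):
                continue               # link condition
            pos = V[u] if prot[u] else 0.5 * (V[u] + V[v])
            nv_o = nv[nv != u]
            if (np.linalg.norm(pos - V[nv_o], axis=1) > max_len).any():
                continue
            V[u] = pos
            remap[v] = u
            face_dead[shared] = True
            touched[u] = touched[v] = True
            touched[nu] = touched[nv] = True
            count += 1
        if count == 0:
            break
        F = remap[F][~face_dead]
        n_collapses += count
    return V, F, labels, prot, n_collapses


# -- flips -------------------------------------------------------------------

def _flip_pass(V, F):
    n = len(V)
    hu, hv, ho, hf = _halfedges(F)
    key = np.minimum(hu, hv).astype(np.int64) * n + np.maximum(hu, hv)
    order = np.argsort(key, kind="stable")
    ks = key[order]
    if len(ks) % 2 or not (ks[0::2] == ks[1::2]).all():
        raise MeshError("flip pass requires a closed manifold mesh")
    h1, h2 = order[0::2], order[1::2]
    u, v = hu[h1], hv[h1]              # f1 holds directed edge u->v
    a, b = ho[h1], ho[h2]
    f1, f2 = hf[h1], hf[h2]
    valence = np.bincount(np.concatenate([u, v]), minlength=n)
    dev = lambda x, val: np.abs(val - 6)
    before = (np.abs(valence[u] - 6) + np.abs(valence[v] - 6)
              + np.abs(valence[a] - 6) + np.abs(valence[b] - 6))
    after = (np.abs(valence[u] - 7) + np.abs(valence[v] - 7)
             + np.abs(valence[a] - 5) + np.abs(valence[b] - 5))
    cand = np.nonzero(after < before)[0]
    if len(cand) == 0:
        return F, 0
    edge_set = set(ks[0::2].tolist())
    face_changed = np.zeros(len(F), dtype=bool)
    n_flips = 0
    F = F.copy()
    for ei in cand:
        uu, vv, aa, bb = int(u[ei]), int(v[ei]), int(a[ei]), int(b[ei])
        ff1, ff2 = int(f1[ei]), int(f2[ei])
        if face_changed[ff1] or face_changed[ff2]:
            continue
        kab = min(aa, bb) * n + max(aa, bb)
        if kab in edge_set:
            continue
        gain = ((abs(valence[uu] - 6) + abs(valence[vv] - 6)
                 + abs(valence[aa] - 6) + abs(valence[bb] - 6))
                - (abs(valence[uu] - 7) + abs(valence[vv] - 7)
                   + abs(valence[aa] - 5) + abs(valence[bb] - 5)))
        if gain <= 0:
            continue
        old_n = (np.cross(V[vv] - V[uu], V[aa] - V[uu])
                 + np.cross(V[uu] - V[vv], V[bb] - V[vv]))
        n1 = np.cross(V[bb] - V[uu], V[aa] - V[uu])
        n2 = np.cross(V[aa] - V[vv], V[bb] - V[vv])
        if (np.linalg.norm(n1) < 1e-16 or np.linalg.norm(n2) < 1e-16
                or np.dot(n1, old_n) <= 0 or np.dot(n2, old_n) <= 0):
            continue
        F[ff1] = (uu, bb, aa)
        F[ff2] = (vv, aa, bb)
        face_changed[ff1] = face_changed[ff2] = True
        edge_set.discard(min(uu, vv) * n + max(uu, vv))
        edge_set.add(kab)
        valence[uu] -= 1; valence[vv] -= 1
        valence[aa] += 1; valence[bb] += 1
        n_flips += 1
    return F, n_flips


# -- tangential relaxation ---------------------------------------------------

def _tangential_relax(V, F, prot, lam):
    if lam <= 0:
        return V
    n = len(V)
    hu, hv, _, _ = _halfedges(F)
    cnt = np.bincount(hu, minlength=n).astype(float)
    cnt[cnt == 0] = 1.0
    centroid = np.empty_like(V)
    for c in range(3):
        centroid[:, c] = np.bincount(hu, weights=V[hv, c],
                                     minlength=n) / cnt
    normals = geom.vertex_normals(V, F)
    d = centroid - V
    d_t = d - np.einsum("ij,ij->i", d, normals)[:, None] * normals
    out = V.copy()
    move = ~prot
    out[move] += lam * d_t[move]
    return out


# -- probe rebinding ---------------------------------------------------------

def rebind_probes(new_mesh: TriMesh, probes, warn_dist: float | None = None):
    """Rebind tracking probes to the nearest vertices of a remeshed surface.

    Probe identity and recorded history are preserved; only the bound vertex
    indices change. Emits a warning when a probe's nearest new vertex is
    farther than ``warn_dist`` (default 2x the median edge length).
    """
    import warnings
    from scipy.spatial import cKDTree

    old_pos = probes.last_positions
    tree = cKDTree(new_mesh.vertices)
    dist, idx = tree.query(old_pos)
    if warn_dist is None:
        warn_dist = 2.0 * float(np.median(new_mesh.edge_lengths()))
    if (dist > warn_dist).any():
        warnings.warn(f"{int((dist > warn_dist).sum())} probe(s) drifted "
                      f"more than {warn_dist:.4g} um during rebinding")
    probes.bound_idx = idx.astype(np.int64)
    probes.last_positions = new_mesh.vertices[probes.bound_idx].copy()
    return probes
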