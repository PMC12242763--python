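"""Enclosed LA volumes by the divergence theorem on capped surfaces.

The LA body is an open surface once the appendage and pulmonary veins
are removed and the mitral annulus is open.  Each boundary loop is
capped with a planar fan lid at its centroid, after which the signed
divergence-theorem volume of the closed surface is exact for the
polyhedron.  LAV and LAEF follow the clinical convention: the LAA and
PVs are excluded.

:class:`VolumeEvaluator` freezes the capped topology once so volume
curves over a cardiac cycle reduce to a vectorized determinant sum.
"""

from __future__ import annotations

import numpy as np

from .mesh import DEFAULT_EXCLUDE, LabeledSurfaceMesh, MeshError


def _boundary_loops(triangles: np.ndarray) -> list[np.ndarray]:
    """Ordered vertex loops of the open boundary; error if not closed cycles."""
    e = np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    und = np.sort(e, axis=1)
    uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    boundary_mask = counts[inv] == 1
    bdir = e[boundary_mask]  # directed boundary edges, winding order preserved
    if len(bdir) == 0:
        return []
    nxt = {}
    for a, b in bdir:
        if a in nxt:
            raise MeshError("non-manifold boundary: cannot order loops")
        nxt[int(a)] = int(b)
    loops = []
    remaining = set(nxt)
    while remaining:
        start = min(remaining)
        loop = [start]
        cur = nxt[start]
        remaining.discard(start)
        while cur != start:
            if cur not in remaining or cur not in nxt:
                raise MeshError("open boundary chain: surface cannot be capped")
            loop.append(cur)
            remaining.discard(cur)
            cur = nxt[cur]
        loops.append(np.asarray(loop, int))
    return loops


def _pinch_vertices(triangles: np.ndarray) -> np.ndarray:
    """Vertices with more than one outgoing directed boundary edge."""
    e = np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    und = np.sort(e, axis=1)
    _, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    bdir = e[counts[inv] == 1]
    if len(bdir) == 0:
        return np.empty(0, int)
    starts, n_out = np.unique(bdir[:, 0], return_counts=True)
    return starts[n_out > 1]


class VolumeEvaluator:
    """Precomputed capped topology for fast repeated volume evaluation.

    Parameters
    ----------
    mesh : LabeledSurfaceMesh
        Labeled surface; triangles touching an excluded label are
        dropped and every resulting boundary loop (incl. the mitral
        rim) is capped with a fan lid to its centroid.
    exclude : iterable of labels
        Structures to remove before capping (default: LAA + 4 PVs).
    """

    def __init__(self, mesh: LabeledSurfaceMesh, exclude=DEFAULT_EXCLUDE):
        excluded_vert = mesh.label_mask(*exclude) if exclude else np.zeros(mesh.n_vertices, bool)
        # removing triangles that touch an excluded vertex can pinch the
        # boundary at single vertices; grow the excluded set there until
        # the boundary is a union of simple loops
        for _ in range(50):
            keep = ~excluded_vert[mesh.triangles].any(axis=1)
            faces = mesh.triangles[keep]
            if len(faces) == 0:
                raise MeshError("no surface left after exclusion")
            pinch = _pinch_vertices(faces)
            if not len(pinch):
                break
            if not excluded_vert.any():
                raise MeshError("non-manifold boundary on the input surface")
            excluded_vert[pinch] = True
        else:
            raise MeshError("could not resolve boundary pinches after exclusion")
        self.kept_faces = faces
        self.loops = _boundary_loops(faces)
        self.n_vertices = mesh.n_vertices
        # cap fans: (loop_id, a, b) triangles (centroid, a, b); boundary
        # directed edges wind opposite to the interior faces, so the fan
        # (c, b, a) matches the surface orientation.
        fans = []
        for li, loop in enumerate(self.loops):
            a = loop
            b = np.roll(loop, -1)
            fans.append(np.column_stack([np.full(len(loop), li), b, a]))
        self.fans = np.concatenate(fans) if fans else np.zeros((0, 3), int)
        self.sign = 1.0
        self.sign = np.sign(self._signed(mesh.vertices)) or 1.0

    def _signed(self, vertices: np.ndarray) -> np.ndarray:
        """Signed volume in mm^3; vertices may be (n,3) or batched (T,n,3)."""
        v = np.asarray(vertices, float)
        f = self.kept_faces
        a, b, c = v[..., f[:, 0], :], v[..., f[:, 1], :], v[..., f[:, 2], :]
        vol = np.einsum("...ij,...ij->...i", a, np.cross(b, c)).sum(axis=-1)
        if len(self.fans):
            centroids = np.stack(
                [v[..., loop, :].mean(axis=-2) for loop in self.loops], axis=-2
            )  # (..., n_loops, 3)
            ca = centroids[..., self.fans[:, 0], :]
            pa = v[..., self.fans[:, 1], :]
            pb = v[..., self.fans[:, 2], :]
            vol = vol + np.einsum("...ij,...ij->...i", ca, np.cross(pa, pb)).sum(axis=-1)
        return vol / 6.0

    def __call__(self, vertices: np.ndarray) -> np.ndarray:
        """Enclosed volume in mL for one vertex array or a (T, n, 3) batch."""
        return self.sign * self._signed(vertices) / 1000.0


def enclosed_volume(
    mesh: LabeledSurfaceMesh, exclude=DEFAULT_EXCLUDE
) -> float:
    """Enclosed volume (mL) of the capped LA body surface.

    The excluded openings and the mitral rim are closed with planar fan
    lids; the result is the divergence-theorem volume of the closed
    oriented polyhedron.  Raises :class:`MeshError` if the remaining
    surface cannot be capped (open chains, non-manifold boundary).
    """
    return float(VolumeEvaluator(mesh, exclude=exclude)(mesh.vertices))


def points_inside(vertices: np.ndarray, faces: np.ndarray, points: np.ndarray,
                  chunk: int = 2048) -> np.ndarray:
    """Containment test by generalized winding number.

    For a closed oriented surface the summed signed solid angle is
    ~4*pi for interior points and ~0 outside (van Oosterom-Strackee
    per-triangle solid angles).  Robust without any spatial index.
    """
    v = np.asarray(vertices, float)
    f = np.asarray(faces, int)
    pts = np.asarray(points, float)
    out = np.empty(len(pts), bool)
    for s in range(0, len(pts), chunk):
        p = pts[s:s + chunk]
        a = v[f[:, 0]][None] - p[:, None]  # (q, m, 3)
        b = v[f[:, 1]][None] - p[:, None]
        c = v[f[:, 2]][None] - p[:, None]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        num = np.einsum("qmi,qmi->qm", a, np.cross(b, c))
        den = (
            la * lb * lc
            + np.einsum("qmi,qmi->qm", a, b) * lc
            + np.einsum("qmi,qmi->qm", b, c) * la
            + np.einsum("qmi,qmi->qm", a, c) * lb
        )
        winding = 2.0 * np.arctan2(num, den).sum(axis=1) / (4.0 * np.pi)
        out[s:s + chunk] = winding > 0.5
    return out


def capped_trimesh(mesh: LabeledSurfaceMesh, exclude=DEFAULT_EXCLUDE):
    """Closed :class:`trimesh.Trimesh` of the capped body (for containment tests)."""
    import trimesh

    ev = VolumeEvaluator(mesh, exclude=exclude)
    v = mesh.vertices
    extra = [v[loop].mean(axis=0) for loop in ev.loops]
    verts = np.vstack([v] + extra) if extra else v.copy()
    fan_faces = np.column_stack(
        [ev.fans[:, 0] + len(v), ev.fans[:, 1], ev.fans[:, 2]]
    ) if len(ev.fans) else np.zeros((0, 3), int)
    faces = np.vstack([ev.kept_faces, fan_faces])
    tm = trimesh.Trimesh(verts, faces, process=False)
    if ev.sign < 0:
        tm.invert()
    return tm
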