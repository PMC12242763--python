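"""Atlas fibre fields and their UAC-based transfer between meshes.

Myocardial fibre directions are stored as one unit tangent vector per
triangle, with separate endocardial and epicardial layers.  A fibre
field defined on an atlas mesh is carried onto any target mesh through
the shared (alpha, beta) chart: each target triangle takes the fibre of
the atlas triangle nearest in coordinate space, re-projected into the
target triangle plane and renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import LabeledSurfaceMesh, MeshError
from .parameterization import UACField


@dataclass
class FibreField:
    """Per-triangle unit tangent vectors (endocardial, optional epicardial)."""

    endo: np.ndarray
    epi: np.ndarray | None = None

    def layers(self):
        out = {"endo": self.endo}
        if self.epi is not None:
            out["epi"] = self.epi
        return out


def _triangle_frames(mesh: LabeledSurfaceMesh):
    v, t = mesh.vertices, mesh.triangles
    e1 = v[t[:, 1]] - v[t[:, 0]]
    e2 = v[t[:, 2]] - v[t[:, 0]]
    n = np.cross(e1, e2)
    nn = np.linalg.norm(n, axis=1)
    if np.any(nn == 0):
        raise MeshError("degenerate triangle in fibre mapping")
    return n / nn[:, None]


def project_to_planes(vectors: np.ndarray, normals: np.ndarray) -> np.ndarray:
    """Project vectors into triangle planes and renormalize."""
    proj = vectors - (vectors * normals).sum(axis=1, keepdims=True) * normals
    nrm = np.linalg.norm(proj, axis=1, keepdims=True)
    # a fibre exactly normal to the plane has no tangential part; keep a
    # deterministic in-plane fallback instead of dividing by zero
    bad = nrm[:, 0] < 1e-12
    if bad.any():
        fallback = np.cross(normals[bad], np.roll(normals[bad], 1, axis=1))
        proj[bad] = fallback
        nrm[bad] = np.linalg.norm(fallback, axis=1, keepdims=True)
    return proj / nrm


def triangle_uac(mesh: LabeledSurfaceMesh, uac: UACField) -> np.ndarray:
    """Per-triangle (alpha, beta), the mean of the vertex coordinates.

    Triangles with any undefined vertex coordinate are NaN.
    """
    a = uac.alpha[mesh.triangles]
    b = uac.beta[mesh.triangles]
    return np.column_stack([a.mean(axis=1), b.mean(axis=1)])


def field_gradients(mesh: LabeledSurfaceMesh, values: np.ndarray) -> np.ndarray:
    """Per-triangle in-plane gradient of a vertex scalar field (linear FEM)."""
    v, t = mesh.vertices, mesh.triangles
    e0 = v[t[:, 2]] - v[t[:, 1]]
    e1 = v[t[:, 0]] - v[t[:, 2]]
    e2 = v[t[:, 1]] - v[t[:, 0]]
    n = np.cross(e2, -e1)
    a2 = np.linalg.norm(n, axis=1, keepdims=True)
    a2[a2 == 0] = 1e-12
    nn = n / a2
    vals = np.asarray(values, float)[t]
    grad = (
        vals[:, [0]] * np.cross(nn, e0)
        + vals[:, [1]] * np.cross(nn, e1)
        + vals[:, [2]] * np.cross(nn, e2)
    ) / a2
    return grad


def map_fibres(
    atlas_mesh: LabeledSurfaceMesh,
    atlas_fibres: FibreField,
    atlas_uac: UACField,
    target_mesh: LabeledSurfaceMesh,
    target_uac: UACField,
) -> FibreField:
    """Transfer an atlas fibre field onto a target mesh via the UAC chart.

    Each target triangle takes the fibre of the atlas triangle nearest
    in (alpha, beta).  The fibre is transported in the chart's local
    tangent frame: its components in the atlas triangle's
    (grad alpha, grad beta) basis are reconstructed in the target
    triangle's basis, then normalized -- so a rigidly moved copy of the
    atlas receives the rigidly moved fibres.  Where the local basis is
    degenerate the fibre falls back to plane projection.  Target
    triangles without valid coordinates (off-body) reuse the nearest
    valid atlas fibre.
    """
    src = triangle_uac(atlas_mesh, atlas_uac)
    dst = triangle_uac(target_mesh, target_uac)
    valid_src = ~np.isnan(src).any(axis=1)
    if not valid_src.any():
        raise MeshError("atlas UAC has no valid triangles")
    tree = cKDTree(src[valid_src])
    dst_filled = np.where(np.isnan(dst), 0.5, dst)
    _, idx = tree.query(dst_filled)
    src_idx = np.where(valid_src)[0][idx]

    # local chart bases on both meshes
    def _bases(mesh, uac):
        a = np.where(np.isnan(uac.alpha), 0.0, uac.alpha)
        b = np.where(np.isnan(uac.beta), 0.0, uac.beta)
        return field_gradients(mesh, a), field_gradients(mesh, b)

    ga_s, gb_s = _bases(atlas_mesh, atlas_uac)
    ga_t, gb_t = _bases(target_mesh, target_uac)
    ga_s, gb_s = ga_s[src_idx], gb_s[src_idx]
    n_s = _triangle_frames(atlas_mesh)[src_idx]
    n_t = _triangle_frames(target_mesh)

    # orthonormal tangent frame (t1, t2 = n x t1) from the stronger
    # chart gradient of the atlas triangle; the same choice is applied
    # on the target so rigid motions transport exactly
    use_alpha = np.linalg.norm(ga_s, axis=1) >= np.linalg.norm(gb_s, axis=1)
    g_s = np.where(use_alpha[:, None], ga_s, gb_s)
    g_t = np.where(use_alpha[:, None], ga_t, gb_t)

    def _frame(g, n):
        nrm = np.linalg.norm(g, axis=1, keepdims=True)
        bad = nrm[:, 0] < 1e-12
        g = g.copy()
        if bad.any():  # chart locally constant: any in-plane direction
            g[bad] = np.cross(n[bad], np.roll(n[bad], 1, axis=1))
            nrm[bad] = np.linalg.norm(g[bad], axis=1, keepdims=True)
        t1 = g / nrm
        t2 = np.cross(n, t1)
        return t1, t2

    t1_s, t2_s = _frame(g_s, n_s)
    t1_t, t2_t = _frame(g_t, n_t)

    layers = {}
    for name, vecs in atlas_fibres.layers().items():
        f = np.asarray(vecs, float)[src_idx]
        rebuilt = (
            (f * t1_s).sum(1, keepdims=True) * t1_t
            + (f * t2_s).sum(1, keepdims=True) * t2_t
        )
        degenerate = np.linalg.norm(rebuilt, axis=1) < 1e-12
        rebuilt[degenerate] = f[degenerate]
        layers[name] = project_to_planes(rebuilt, n_t)
    return FibreField(endo=layers["endo"], epi=layers.get("epi"))


def rule_based_fibres(mesh: LabeledSurfaceMesh, axis=(0.0, 0.0, 1.0)) -> FibreField:
    """Simple circumferential fibre field for synthetic atlases.

    Endocardial fibres run circumferentially around ``axis``; the
    epicardial layer is rotated ~60 degrees toward the axis within the
    triangle plane, echoing the transmural fibre rotation seen in
    atlas-derived atrial fields.
    """
    normals = _triangle_frames(mesh)
    axis = np.asarray(axis, float)
    circ = project_to_planes(np.cross(np.broadcast_to(axis, normals.shape), normals), normals)
    axial = project_to_planes(np.broadcast_to(axis, normals.shape).copy(), normals)
    c, s = np.cos(np.deg2rad(60.0)), np.sin(np.deg2rad(60.0))
    epi = project_to_planes(c * circ + s * axial, normals)
    return FibreField(endo=circ, epi=epi)
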