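"""Labeled triangulated surface meshes of the left atrium.

The central data model is :class:`LabeledSurfaceMesh`: a triangulated
surface of the LA endocardium in millimetres, with one anatomical label
per vertex (LA body, the four pulmonary veins, the appendage, and the
mitral rim) and named landmark vertex sets (PV--LA junction rings and
the anchor sets used to pose the Laplace parameterization).

Meshes are exchanged as legacy-ASCII VTK polydata (point/cell data
arrays carry labels, coordinates, regions and intensities) or as PLY
with a JSON sidecar for labels and landmarks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

#: Valid per-vertex anatomical labels.
VERTEX_LABELS = ("body", "LSPV", "LIPV", "RSPV", "RIPV", "LAA", "mitral_rim")

#: The four pulmonary-vein labels, left then right.
PV_LABELS = ("LSPV", "LIPV", "RSPV", "RIPV")
LEFT_PV_LABELS = ("LSPV", "LIPV")
RIGHT_PV_LABELS = ("RSPV", "RIPV")
APPENDAGE_LABEL = "LAA"

#: Structures excluded from the LA body when computing LAV/LAEF.
DEFAULT_EXCLUDE = PV_LABELS + (APPENDAGE_LABEL,)


class MeshError(ValueError):
    """Raised when a surface violates the labeled-mesh contract."""


@dataclass
class LabeledSurfaceMesh:
    """Triangulated LA surface with per-vertex anatomical labels.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in millimetres.
    triangles : (m, 3) int array
        Vertex index triplets, counter-clockwise when viewed from
        outside the chamber.
    vertex_labels : (n,) str array
        One label per vertex, drawn from :data:`VERTEX_LABELS`.
    landmarks : dict of str -> int array
        Named vertex sets: PV junction rings (``"<PV>_junction"``),
        and the Dirichlet anchor sets ``alpha_0/alpha_1/beta_0/beta_1``.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    vertex_labels: np.ndarray
    landmarks: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        self.vertex_labels = np.asarray(self.vertex_labels, dtype="U12")
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError("triangles must be (m, 3)")
        if self.vertex_labels.shape != (len(self.vertices),):
            raise MeshError("need exactly one label per vertex")
        self.landmarks = {
            k: np.asarray(v, dtype=np.int64) for k, v in self.landmarks.items()
        }

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def label_mask(self, *labels: str) -> np.ndarray:
        """Boolean vertex mask for any of the given labels."""
        return np.isin(self.vertex_labels, labels)

    @property
    def body_mask(self) -> np.ndarray:
        return self.vertex_labels == "body"

    def triangle_areas(self, vertices: np.ndarray | None = None) -> np.ndarray:
        """Per-triangle areas in mm^2 (optionally for alternative positions)."""
        v = self.vertices if vertices is None else np.asarray(vertices, float)
        return triangle_areas(v, self.triangles)

    def triangle_normals(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length)."""
        v, t = self.vertices, self.triangles
        fn = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        vn = np.zeros_like(v)
        for k in range(3):
            np.add.at(vn, t[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vn / norm

    def unique_edges(self) -> np.ndarray:
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def boundary_edges(self) -> np.ndarray:
        """Undirected edges belonging to exactly one triangle."""
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    def as_trimesh(self) -> trimesh.Trimesh:
        """View as a :class:`trimesh.Trimesh` without reprocessing."""
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    def copy(self) -> "LabeledSurfaceMesh":
        return LabeledSurfaceMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            self.vertex_labels.copy(),
            {k: v.copy() for k, v in self.landmarks.items()},
        )

    def with_vertices(self, vertices: np.ndarray) -> "LabeledSurfaceMesh":
        """Same connectivity, labels and landmarks with new positions."""
        out = self.copy()
        out.vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        if out.vertices.shape != self.vertices.shape:
            raise MeshError("replacement vertices must match shape")
        return out

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self, require_connected: bool = True) -> None:
        """Check the labeled-mesh invariants, raising MeshError on failure.

        Checks: labels are valid; all triangle areas strictly positive;
        each edge borders at most two triangles with consistent winding
        (orientable 2-manifold with boundary); the surface is connected.
        """
        bad = set(np.unique(self.vertex_labels)) - set(VERTEX_LABELS)
        if bad:
            raise MeshError(f"unknown vertex labels: {sorted(bad)}")
        if self.triangles.min(initial=0) < 0 or self.triangles.max(initial=-1) >= self.n_vertices:
            raise MeshError("triangle indices out of range")
        if np.any(self.triangle_areas() <= 0):
            raise MeshError("degenerate triangle with non-positive area")

        directed = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        uniq, counts = np.unique(directed, axis=0, return_counts=True)
        if np.any(counts > 1):
            raise MeshError("inconsistent winding or non-manifold edge")
        und = np.sort(directed, axis=1)
        _, ucounts = np.unique(und, axis=0, return_counts=True)
        if np.any(ucounts > 2):
            raise MeshError("edge shared by more than two triangles")

        if require_connected:
            import scipy.sparse as sp
            from scipy.sparse.csgraph import connected_components

            e = self.unique_edges()
            adj = sp.coo_matrix(
                (np.ones(len(e)), (e[:, 0], e[:, 1])),
                shape=(self.n_vertices, self.n_vertices),
            )
            n_comp, _ = connected_components(adj, directed=False)
            if n_comp != 1:
                raise MeshError(f"mesh has {n_comp} connected components")

        for name, idx in self.landmarks.items():
            if len(idx) and (idx.min() < 0 or idx.max() >= self.n_vertices):
                raise MeshError(f"landmark {name!r} indices out of range")


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Areas of triangles; supports batched vertices of shape (..., n, 3)."""
    v = np.asarray(vertices, float)
    a = v[..., triangles[:, 0], :]
    b = v[..., triangles[:, 1], :]
    c = v[..., triangles[:, 2], :]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=-1)


# ----------------------------------------------------------------------
# legacy-ASCII VTK polydata I/O
# ----------------------------------------------------------------------

def write_vtk(
    path,
    vertices: np.ndarray,
    triangles: np.ndarray,
    point_data: dict | None = None,
    cell_data: dict | None = None,
    comment: str = "lastrain surface",
) -> None:
    """Write a legacy-ASCII VTK polydata file with optional data arrays.

    Scalar arrays are written as SCALARS, (n, 3) arrays as VECTORS.
    """
    vertices = np.asarray(vertices, float)
    triangles = np.asarray(triangles, int)
    lines = [
        "# vtk DataFile Version 3.0",
        comment,
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(vertices)} float",
    ]
    lines += [" ".join(f"{x:.9g}" for x in row) for row in vertices]
    lines.append(f"POLYGONS {len(triangles)} {4 * len(triangles)}")
    lines += ["3 " + " ".join(str(i) for i in row) for row in triangles]

    def _emit(block: dict, header: str, n: int):
        lines.append(f"{header} {n}")
        for name, arr in block.items():
            arr = np.asarray(arr)
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} float")
                lines.extend(" ".join(f"{x:.9g}" for x in row) for row in arr)
            else:
                dtype = "int" if np.issubdtype(arr.dtype, np.integer) else "float"
                lines.append(f"SCALARS {name} {dtype} 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(
                    f"{x:.9g}" if dtype == "float" else str(int(x)) for x in arr
                )

    if point_data:
        _emit(point_data, "POINT_DATA", len(vertices))
    if cell_data:
        _emit(cell_data, "CELL_DATA", len(triangles))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk(path):
    """Read a legacy-ASCII VTK polydata file written by :func:`write_vtk`.

    Returns ``(vertices, triangles, point_data, cell_data)``.
    """
    tokens = Path(path).read_text().split("\n")
    it = iter(range(len(tokens)))
    i = 0

    def line():
        nonlocal i
        while i < len(tokens) and not tokens[i].strip():
            i += 1
        out = tokens[i]
        i += 1
        return out

    header = line()
    if not header.startswith("# vtk"):
        raise MeshError(f"{path}: not a legacy VTK file")
    line()  # comment
    if line().strip() != "ASCII":
        raise MeshError(f"{path}: only ASCII VTK supported")
    if line().split()[0] != "DATASET":
        raise MeshError(f"{path}: missing DATASET")

    n_pts = int(line().split()[1])
    vertices = np.array([line().split() for _ in range(n_pts)], dtype=float)
    poly = line().split()
    n_tri = int(poly[1])
    triangles = np.array([line().split()[1:] for _ in range(n_tri)], dtype=int)

    point_data: dict = {}
    cell_data: dict = {}
    current = None
    current_n = 0
    while i < len(tokens):
        raw = tokens[i].strip()
        i += 1
        if not raw:
            continue
        parts = raw.split()
        if parts[0] == "POINT_DATA":
            current, current_n = point_data, int(parts[1])
        elif parts[0] == "CELL_DATA":
            current, current_n = cell_data, int(parts[1])
        elif parts[0] == "SCALARS":
            name, dtype = parts[1], parts[2]
            line()  # LOOKUP_TABLE
            vals = [line() for _ in range(current_n)]
            current[name] = np.array(vals, dtype=int if dtype == "int" else float)
        elif parts[0] == "VECTORS":
            name = parts[1]
            vals = [line().split() for _ in range(current_n)]
            current[name] = np.array(vals, dtype=float)
    return vertices, triangles, point_data, cell_data


_LABEL_CODES = {lab: k for k, lab in enumerate(VERTEX_LABELS)}


def save_mesh(mesh: LabeledSurfaceMesh, path, extra_point_data: dict | None = None) -> None:
    """Persist a labeled mesh: VTK polydata plus a JSON landmark sidecar."""
    path = Path(path)
    codes = np.array([_LABEL_CODES[l] for l in mesh.vertex_labels], dtype=int)
    pdata = {"label": codes}
    if extra_point_data:
        pdata.update(extra_point_data)
    write_vtk(path, mesh.vertices, mesh.triangles, point_data=pdata)
    side = {name: idx.tolist() for name, idx in mesh.landmarks.items()}
    path.with_suffix(".landmarks.json").write_text(json.dumps(side))


def load_mesh(path) -> LabeledSurfaceMesh:
    """Load a mesh written by :func:`save_mesh`."""
    path = Path(path)
    vertices, triangles, pdata, _ = read_vtk(path)
    if "label" not in pdata:
        raise MeshError(f"{path}: missing 'label' point-data array")
    labels = np.array([VERTEX_LABELS[int(c)] for c in pdata["label"]], dtype="U12")
    landmarks = {}
    side = path.with_suffix(".landmarks.json")
    if side.exists():
        landmarks = {k: np.asarray(v, int) for k, v in json.loads(side.read_text()).items()}
    return LabeledSurfaceMesh(vertices, triangles, labels, landmarks)


def save_ply(mesh: LabeledSurfaceMesh, path) -> None:
    """Export geometry as ASCII PLY with a JSON sidecar for labels/landmarks."""
    path = Path(path)
    tm = mesh.as_trimesh()
    path.write_bytes(trimesh.exchange.ply.export_ply(tm, encoding="ascii"))
    side = {
        "vertex_labels": mesh.vertex_labels.tolist(),
        "landmarks": {k: v.tolist() for k, v in mesh.landmarks.items()},
    }
    path.with_suffix(".labels.json").write_text(json.dumps(side))


def load_ply(path) -> LabeledSurfaceMesh:
    path = Path(path)
    tm = trimesh.load(path, process=False)
    side = json.loads(path.with_suffix(".labels.json").read_text())
    return LabeledSurfaceMesh(
        np.asarray(tm.vertices, float),
        np.asarray(tm.faces, int),
        np.asarray(side["vertex_labels"], dtype="U12"),
        {k: np.asarray(v, int) for k, v in side["landmarks"].items()},
    )
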