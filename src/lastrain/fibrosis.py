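"""LGE fibrosis quantification on the LA surface.

Enhancement is defined by the image intensity ratio (IIR): per-vertex
LGE intensity divided by the mean blood-pool intensity, thresholded at
1.2.  A region's enhancement is the percentage of its surface area
whose triangles are above threshold; regions are staged 1-4 by the
<10 / 10-20 / 20-30 / >30 % cut points, and stage 4 (> 30 %, strictly)
is "severe" fibrosis.

Stage intervals are half-open on the left cut: [0,10) -> 1, [10,20)
-> 2, [20,30] -> 3, and stage 4 requires enhancement strictly above
the severe cut, so exactly 30 % is stage 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import LabeledSurfaceMesh
from .parameterization import REGIONS


class FibrosisError(ValueError):
    pass


@dataclass
class FibrosisConfig:
    """Thresholds for enhancement detection and staging.

    iir_threshold : IIR above which tissue counts as enhanced (1.2).
    stage_bounds : % cut points between stages 1|2, 2|3, 3|4.
    triangle_rule : how a triangle's enhancement is decided --
        ``"mean_vertex"`` (mean of its three vertex IIRs above
        threshold) or ``"vertex_share"`` (each above-threshold vertex
        contributes a third of the triangle area).
    projection_depth_mm : half-length of the normal ray used when
        projecting image intensities onto the surface.
    """

    iir_threshold: float = 1.2
    stage_bounds: tuple = (10.0, 20.0, 30.0)
    triangle_rule: str = "mean_vertex"
    projection_depth_mm: float = 3.0

    def __post_init__(self):
        if self.iir_threshold <= 0:
            raise FibrosisError("iir_threshold must be positive")
        b = self.stage_bounds
        if not (len(b) == 3 and b[0] < b[1] < b[2]):
            raise FibrosisError("stage_bounds must be three increasing cut points")


@dataclass
class RegionalFibrosisMap:
    """Per-region enhancement %, stage 1-4 and severe flag."""

    enhancement_pct: dict = field(default_factory=dict)
    stage: dict = field(default_factory=dict)
    severe: dict = field(default_factory=dict)

    def to_frame(self, subject: str | None = None) -> pd.DataFrame:
        rows = [
            {
                "region": r,
                "enhancement_pct": self.enhancement_pct[r],
                "stage": self.stage[r],
                "severe": self.severe[r],
            }
            for r in self.enhancement_pct
        ]
        df = pd.DataFrame(rows)
        if subject is not None:
            df.insert(0, "subject", subject)
        return df


def stage(enhancement_pct: float, config: FibrosisConfig | None = None) -> tuple[int, bool]:
    """Fibrosis stage (1-4) and severe flag for an enhancement percentage."""
    config = config or FibrosisConfig()
    p = float(enhancement_pct)
    if not 0.0 <= p <= 100.0:
        raise FibrosisError(f"enhancement {p} outside [0, 100]")
    b1, b2, b3 = config.stage_bounds
    if p > b3:
        return 4, True
    if p >= b2:
        return 3, False
    if p >= b1:
        return 2, False
    return 1, False


def compute_iir(vertex_intensity: np.ndarray, blood_pool_mean: float) -> np.ndarray:
    """Image intensity ratio: intensity normalized by mean blood-pool signal."""
    if blood_pool_mean <= 0:
        raise FibrosisError("blood_pool_mean must be positive")
    return np.asarray(vertex_intensity, float) / float(blood_pool_mean)


def triangle_enhanced_area(
    mesh: LabeledSurfaceMesh,
    iir: np.ndarray,
    config: FibrosisConfig,
) -> np.ndarray:
    """Enhanced area contribution of every triangle, in mm^2."""
    areas = mesh.triangle_areas()
    tri_iir = np.asarray(iir, float)[mesh.triangles]  # (m, 3)
    if config.triangle_rule == "mean_vertex":
        return areas * (tri_iir.mean(axis=1) > config.iir_threshold)
    if config.triangle_rule == "vertex_share":
        return areas * (tri_iir > config.iir_threshold).mean(axis=1)
    raise FibrosisError(f"unknown triangle_rule {config.triangle_rule!r}")


def regional_enhancement(
    mesh: LabeledSurfaceMesh,
    iir: np.ndarray,
    tri_regions: np.ndarray,
    config: FibrosisConfig | None = None,
) -> RegionalFibrosisMap:
    """Quantify per-region % enhancement and stage it.

    enhancement_pct = 100 * enhanced regional area / total regional
    area, with the enhanced decision per triangle set by the config's
    ``triangle_rule``.
    """
    config = config or FibrosisConfig()
    iir = np.asarray(iir, float)
    if len(iir) != mesh.n_vertices:
        raise FibrosisError("iir must be a per-vertex array")
    enhanced = triangle_enhanced_area(mesh, iir, config)
    areas = mesh.triangle_areas()

    out = RegionalFibrosisMap()
    for reg in REGIONS:
        mask = tri_regions == reg
        if not mask.any():
            raise FibrosisError(f"region {reg!r} is empty")
        pct = 100.0 * enhanced[mask].sum() / areas[mask].sum()
        st, sev = stage(pct, config)
        out.enhancement_pct[reg] = float(pct)
        out.stage[reg] = st
        out.severe[reg] = bool(sev)
    return out


def whole_surface_enhancement(
    mesh: LabeledSurfaceMesh, iir: np.ndarray, tri_regions: np.ndarray,
    config: FibrosisConfig | None = None,
) -> float:
    """% enhancement over all body triangles (area-weighted)."""
    config = config or FibrosisConfig()
    enhanced = triangle_enhanced_area(mesh, iir, config)
    areas = mesh.triangle_areas()
    body = tri_regions != ""
    return float(100.0 * enhanced[body].sum() / areas[body].sum())


# ----------------------------------------------------------------------
# image <-> surface
# ----------------------------------------------------------------------

def _world_to_voxel(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    return points @ inv[:3, :3].T + inv[:3, 3]


def project_image_to_surface(
    image,
    mesh: LabeledSurfaceMesh,
    depth_mm: float | None = None,
    n_samples: int = 9,
) -> np.ndarray:
    """Sample an LGE image onto mesh vertices.

    For each vertex, the image is trilinearly sampled along the outward
    vertex normal over [-depth, +depth] and the maximum is kept
    (bright-rim capture).  ``image`` is a nibabel spatial image or a
    ``(data, affine)`` pair.  A vertex whose entire sampling ray falls
    outside the image raises an error naming the vertex.
    """
    from scipy.ndimage import map_coordinates

    if hasattr(image, "get_fdata"):
        data = np.asarray(image.get_fdata(), float)
        affine = image.affine
    else:
        data, affine = image
        data = np.asarray(data, float)
    if depth_mm is None:
        depth_mm = FibrosisConfig().projection_depth_mm

    normals = mesh.vertex_normals()
    if depth_mm == 0:
        offsets = np.array([0.0])
    else:
        offsets = np.linspace(-depth_mm, depth_mm, n_samples)
    pts = mesh.vertices[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    vox = _world_to_voxel(affine, pts.reshape(-1, 3))
    vals = map_coordinates(
        data, vox.T, order=1, mode="constant", cval=np.nan
    ).reshape(len(offsets), mesh.n_vertices)
    out = np.full(mesh.n_vertices, np.nan)
    with np.errstate(all="ignore"):
        valid = ~np.isnan(vals).all(axis=0)
        out[valid] = np.nanmax(vals[:, valid], axis=0)
    if not valid.all():
        bad = int(np.where(~valid)[0][0])
        raise FibrosisError(f"vertex {bad} samples entirely outside the image")
    return out


def estimate_blood_pool_mean(
    image,
    mesh: LabeledSurfaceMesh,
    erosion_mm: float | None = None,
    max_samples: int = 4000,
) -> float:
    """Mean cavity intensity, sampled inside the capped LA body.

    Voxel centers inside the capped body and farther than
    ``erosion_mm`` (default: the projection depth) from the surface are
    averaged; wall-adjacent samples are discarded so myocardial signal
    does not bias the blood-pool reference.
    """
    from .strain import closest_points_on_surface
    from .volume import capped_trimesh, points_inside

    if hasattr(image, "get_fdata"):
        data = np.asarray(image.get_fdata(), float)
        affine = image.affine
    else:
        data, affine = image
        data = np.asarray(data, float)
    if erosion_mm is None:
        erosion_mm = FibrosisConfig().projection_depth_mm

    tm = capped_trimesh(mesh)
    ijk = np.stack(
        np.meshgrid(*[np.arange(s) for s in data.shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    world = ijk @ affine[:3, :3].T + affine[:3, 3]
    inside_box = np.all((world > tm.bounds[0]) & (world < tm.bounds[1]), axis=1)
    cand_idx = np.where(inside_box)[0]
    if len(cand_idx) > max_samples:
        stride = int(np.ceil(len(cand_idx) / max_samples))
        cand_idx = cand_idx[::stride]
    pts = world[cand_idx]
    inside = points_inside(tm.vertices, tm.faces, pts)
    pts = pts[inside]
    vals = data.reshape(-1)[cand_idx][inside]
    if len(pts) == 0:
        raise FibrosisError("no cavity samples inside the mesh")
    _, dist = closest_points_on_surface(np.asarray(tm.vertices), np.asarray(tm.faces), pts)
    keep = dist > erosion_mm
    if not keep.any():
        raise FibrosisError("no cavity samples remain after wall erosion")
    return float(vals[keep].mean())
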