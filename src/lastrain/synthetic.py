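"""Synthetic LA cohort generator.

Builds seeded, fully labeled atrial anatomies (ellipsoidal body with
radially extruded PV and LAA stubs and an open mitral annulus), cyclic
vertex-corresponded motion with reservoir/conduit/booster phases,
LGE-like vertex intensity fields with painted fibrotic patches, and
two-cohort datasets with the statistical structure the downstream
analysis assumes:

* regional reservoir strain is drawn per subject and region from a
  gamma distribution matching the cohort mean/SD (healthy 48.0 +- 33.2 %,
  AF 19.5 +- 15.7 %), independent of everything else by default;
* severe fibrosis per region follows a logistic model in standardized
  LAV, LAEF and region indicators, with the highest burden in the
  lateral and posterior walls -- so strain carries no information about
  severity unless ``strain_fibrosis_coupling`` is switched on;
* every stored "truth" value is measured from the generated surfaces
  and intensities with the same package operations the pipeline uses,
  so truth/pipeline closure holds by construction.

All operations are bitwise deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree

from .fibrosis import FibrosisConfig, regional_enhancement, stage
from .mesh import DEFAULT_EXCLUDE, LabeledSurfaceMesh
from .parameterization import (
    REGIONS,
    RegionThresholds,
    UACField,
    assign_regions,
    build_uac,
    triangle_regions,
)
from .strain import MeshMotion, regional_strain_curves
from .volume import VolumeEvaluator, enclosed_volume


class GeneratorError(ValueError):
    pass


# ----------------------------------------------------------------------
# cohort specification
# ----------------------------------------------------------------------

#: Relative regional reservoir-strain weights (mean 1): the septum is
#: the strongest wall, the PV antra the weakest.
REGION_RS_WEIGHTS = {
    "septal": 1.25,
    "anterior": 1.05,
    "posterior": 1.0,
    "lateral": 1.0,
    "RPVA": 0.90,
    "LPVA": 0.80,
}

#: Mean regional enhancement (%) in the AF cohort; RPVA is a declared
#: default between LPVA and anterior.
AF_FIBROSIS_BASE = {
    "lateral": 44.4,
    "posterior": 40.9,
    "septal": 32.7,
    "anterior": 31.4,
    "RPVA": 29.0,
    "LPVA": 26.0,
}

#: Additive region terms on the severe-fibrosis log-odds, tuned so the
#: marginal AF prevalence pattern peaks in the lateral and posterior
#: walls (~85 % and ~66 % of subjects).
REGION_SEVERE_OFFSETS = {
    "lateral": 1.8,
    "posterior": 0.60,
    "septal": 0.05,
    "anterior": -0.05,
    "RPVA": -0.4,
    "LPVA": -0.85,
}


@dataclass
class CohortSpec:
    """Generator settings defining one simulated cohort."""

    n_subjects: int = 10
    cohort: str = "AF"
    seed: int = 0
    frames_per_cycle: int = 30
    subdivisions: int = 3

    # regional reservoir strain, pooled over (subject, region)
    regional_rs_mean: float = 19.5
    regional_rs_sd: float = 15.7
    region_rs_weights: dict = field(default_factory=lambda: dict(REGION_RS_WEIGHTS))

    # global anatomy / function
    lav_mean: float = 105.0
    lav_sd: float = 25.0
    lav_bounds: tuple = (50.0, 200.0)
    laef_mean: float = 32.0
    laef_sd: float = 10.0
    laef_bounds: tuple = (8.0, 65.0)

    # fibrosis model
    fibrosis_region_base: dict = field(default_factory=lambda: dict(AF_FIBROSIS_BASE))
    fibrosis_sd: float = 18.0
    severe_intercept: float = 0.60
    region_offsets: dict = field(default_factory=lambda: dict(REGION_SEVERE_OFFSETS))
    link_coefficients: dict = field(default_factory=lambda: {"lav": 2.0, "laef": -2.0})
    strain_fibrosis_coupling: float = 0.0
    healthy_severe_cap: float = 0.10

    # signal model
    blood_pool_mean: float = 100.0
    enhanced_iir: float = 1.5
    background_iir: float = 0.9
    intensity_noise_sd: float = 3.0  # absolute intensity units
    motion_jitter_mm: float = 0.02
    nonbody_motion_factor: float = 0.5  # PV/LAA amplitude relative to body mean

    antra_radius_mm: float = 10.0

    # wall corrugation: high-frequency radial texture baked into the
    # reference wall that deepens or flattens over the cycle, giving
    # the generator independent control of surface area (strain) and
    # enclosed volume (LAEF)
    wrinkle_depth: float = 0.10

    def __post_init__(self):
        if self.n_subjects < 1:
            raise GeneratorError("n_subjects must be >= 1")
        if self.frames_per_cycle < 3:
            raise GeneratorError("frames_per_cycle must be >= 3")
        if not 0.0 <= self.healthy_severe_cap <= 1.0:
            raise GeneratorError("healthy_severe_cap must be a probability")

    @classmethod
    def preset(cls, cohort: str, n_subjects: int, seed: int = 0, **overrides) -> "CohortSpec":
        """Cohort presets: ``healthy``, ``AF`` or ``DCM``."""
        base = dict(n_subjects=n_subjects, cohort=cohort, seed=seed)
        if cohort == "healthy":
            base.update(
                regional_rs_mean=48.0, regional_rs_sd=33.2,
                lav_mean=68.0, lav_sd=12.0, lav_bounds=(35.0, 120.0),
                laef_mean=52.0, laef_sd=7.0, laef_bounds=(30.0, 70.0),
                severe_intercept=-6.0,
                fibrosis_region_base={r: 0.35 * v for r, v in AF_FIBROSIS_BASE.items()},
                fibrosis_sd=10.0,
            )
        elif cohort == "AF":
            pass  # the dataclass defaults are the AF conditions
        elif cohort == "DCM":
            base.update(
                regional_rs_mean=30.0, regional_rs_sd=20.0,
                lav_mean=85.0, lav_sd=20.0, lav_bounds=(40.0, 160.0),
                laef_mean=40.0, laef_sd=10.0, laef_bounds=(12.0, 68.0),
                severe_intercept=-0.8,
                fibrosis_region_base={r: 0.8 * v for r, v in AF_FIBROSIS_BASE.items()},
            )
        else:
            raise GeneratorError(f"unknown cohort preset {cohort!r}")
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lav_bounds"] = list(self.lav_bounds)
        d["laef_bounds"] = list(self.laef_bounds)
        return d


@dataclass
class SyntheticSubject:
    """One generated subject with measured ground truth."""

    subject_id: str
    anatomy: LabeledSurfaceMesh
    uac: UACField
    regions: np.ndarray
    tri_regions: np.ndarray
    motion: MeshMotion
    vertex_intensity: np.ndarray
    blood_pool_mean: float
    center: np.ndarray
    truth: dict


# ----------------------------------------------------------------------
# anatomy
# ----------------------------------------------------------------------

_PV_DIRECTIONS = {
    "LSPV": np.array([-0.62, -0.50, 0.60]),
    "LIPV": np.array([-0.80, -0.52, -0.02]),
    "RSPV": np.array([0.62, -0.50, 0.60]),
    "RIPV": np.array([0.80, -0.52, -0.02]),
}
_LAA_DIRECTION = np.array([-0.55, 0.66, 0.45])
_PV_PATCH_RAD = 0.26
_PV_HOLE_RAD = 0.11
_LAA_PATCH_RAD = 0.32
_LAA_HOLE_RAD = 0.13
_MITRAL_Z = -0.80
_ANCHOR_K = 12


def _unit(v):
    return v / np.linalg.norm(v)


def _wrinkle_signs(faces: np.ndarray, n: int) -> np.ndarray:
    """Greedy +-1 vertex coloring: neighbours get opposite signs where
    possible (triangle meshes are not bipartite, so some edges tie)."""
    neighbors = [[] for _ in range(n)]
    for t3 in faces:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            neighbors[t3[a]].append(int(t3[b]))
            neighbors[t3[b]].append(int(t3[a]))
    eta = np.zeros(n, int)
    for v in range(n):
        s = sum(eta[w] for w in neighbors[v])
        eta[v] = -1 if s > 0 else 1
    return eta.astype(float)


def generate_anatomy(
    spec: CohortSpec | None = None,
    subject_seed: int = 0,
    target_volume_ml: float | None = None,
) -> LabeledSurfaceMesh:
    """Build one labeled LA anatomy.

    The surface is an icosphere deformed to an ellipsoid, with the four
    PVs and the LAA realized as radially extruded stubs opened at their
    tips, and the mitral annulus opened at the inferior pole.  The
    anatomy is uniformly rescaled so that the capped LA body volume
    (LAA/PVs excluded) equals ``target_volume_ml`` exactly; by
    convention this is the minimum (LVED) volume of the cycle.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng([int(spec.seed), int(subject_seed), 0])

    sphere = trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=1.0)
    u = np.asarray(sphere.vertices, float)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    faces = np.asarray(sphere.faces, int)
    n = len(u)

    labels = np.full(n, "body", dtype="U12")
    remove = np.zeros(n, bool)
    bump = np.zeros(n)

    patches = {lab: (_unit(d), _PV_PATCH_RAD, _PV_HOLE_RAD, 0.30)
               for lab, d in _PV_DIRECTIONS.items()}
    patches["LAA"] = (_unit(_LAA_DIRECTION), _LAA_PATCH_RAD, _LAA_HOLE_RAD, 0.35)

    for lab, (d, patch_r, hole_r, height) in patches.items():
        ang = np.arccos(np.clip(u @ d, -1, 1))
        in_patch = ang < patch_r
        if labels[in_patch].size and np.any(labels[in_patch] != "body"):
            raise GeneratorError("overlapping PV/LAA patches")
        labels[in_patch] = lab
        remove |= ang < hole_r
        f = np.cos(0.5 * np.pi * np.clip(ang / patch_r, 0, 1)) ** 2
        bump = np.maximum(bump, height * f * in_patch)

    remove |= u[:, 2] < _MITRAL_Z

    keep = ~remove
    index_map = -np.ones(n, int)
    index_map[keep] = np.arange(keep.sum())
    tri_keep = keep[faces].all(axis=1)
    faces2 = index_map[faces[tri_keep]]
    u2 = u[keep]
    labels2 = labels[keep]
    bump2 = bump[keep]

    # mitral rim: boundary loop nearest the inferior pole
    from .volume import _boundary_loops

    for loop in _boundary_loops(faces2):
        if u2[loop, 2].mean() < -0.5:
            labels2[loop] = "mitral_rim"

    # subject-specific ellipsoid axes
    axes = np.array([1.05, 0.92, 1.00]) * (1.0 + np.clip(rng.normal(0, 0.04, 3), -0.1, 0.1))
    radius = 28.0

    # wall corrugation: alternate-sign radial texture on the body,
    # assigned by greedy graph 2-coloring so neighbouring vertices tend
    # to carry opposite signs (high spatial frequency)
    eta = _wrinkle_signs(faces2, len(u2))
    eta[labels2 != "body"] = 0
    rho = 1.0 + spec.wrinkle_depth * eta

    verts = u2 * ((1.0 + bump2) * rho)[:, None] * axes[None, :] * radius

    # landmarks: junction rings and harmonic anchor sets
    landmarks = {}
    edge_pairs = np.concatenate([faces2[:, [0, 1]], faces2[:, [1, 2]], faces2[:, [2, 0]]])
    body_mask = labels2 == "body"
    for lab in list(_PV_DIRECTIONS) + ["LAA"]:
        lab_mask = labels2 == lab
        touching = lab_mask[edge_pairs]
        ring = np.unique(
            np.concatenate(
                [edge_pairs[touching[:, 1], 0], edge_pairs[touching[:, 0], 1]]
            )
        )
        ring = ring[body_mask[ring]]
        landmarks[f"{lab}_junction"] = ring

    body_idx = np.where(body_mask)[0]
    order_x = body_idx[np.argsort(u2[body_idx, 0], kind="stable")]
    order_y = body_idx[np.argsort(u2[body_idx, 1], kind="stable")]
    landmarks["alpha_0"] = np.sort(order_x[:_ANCHOR_K])       # lateral
    landmarks["alpha_1"] = np.sort(order_x[-_ANCHOR_K:])      # septal
    landmarks["beta_0"] = np.sort(order_y[:_ANCHOR_K])        # posterior
    landmarks["beta_1"] = np.sort(order_y[-_ANCHOR_K:])       # anterior
    landmarks["wrinkle_positive"] = np.where(eta > 0)[0]

    mesh = LabeledSurfaceMesh(verts, faces2, labels2, landmarks)

    if target_volume_ml is not None:
        if target_volume_ml <= 0:
            raise GeneratorError("target_volume_ml must be positive")
        vol = enclosed_volume(mesh, DEFAULT_EXCLUDE)
        mesh.vertices *= (target_volume_ml / vol) ** (1.0 / 3.0)
    return mesh


# ----------------------------------------------------------------------
# subject-level draws
# ----------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def subject_draws(spec: CohortSpec, subject_seed: int) -> dict:
    """Draw the latent per-subject truth: LAV_max, LAEF and regional RS.

    Regional RS is gamma-distributed (non-negative, first two moments
    matched to the cohort mean/SD) with mild regional weighting;
    independent of LAV and LAEF.
    """
    rng = np.random.default_rng([int(spec.seed), int(subject_seed), 1])
    lav = _truncated_normal(rng, spec.lav_mean, spec.lav_sd, *spec.lav_bounds)
    laef = _truncated_normal(rng, spec.laef_mean, spec.laef_sd, *spec.laef_bounds)
    weights = np.array([spec.region_rs_weights[r] for r in REGIONS])
    weights = weights / weights.mean()
    rs = {}
    for r, w in zip(REGIONS, weights):
        m = spec.regional_rs_mean * w
        sd = spec.regional_rs_sd
        shape = (m / sd) ** 2
        scale = sd ** 2 / m
        rs[r] = float(rng.gamma(shape, scale))
    return {"lav_max_ml": lav, "laef_pct": laef, "rs_targets": rs}


# ----------------------------------------------------------------------
# motion
# ----------------------------------------------------------------------

def _cycle_envelope(t: np.ndarray, booster_weight: float = 0.25) -> np.ndarray:
    """Smooth biphasic filling envelope, 0 at LVED, max 1 mid-cycle.

    Sum of two periodic Gaussian bumps: the reservoir filling peak near
    40 % of the cycle and a late-diastolic shoulder before booster
    ejection.
    """
    def pbump(c, s):
        d = np.minimum(np.abs(t - c), 1.0 - np.abs(t - c))
        return np.exp(-0.5 * (d / s) ** 2)

    g = (1.0 - booster_weight) * pbump(0.40, 0.15) + booster_weight * pbump(0.70, 0.10)
    g = np.clip(g - g[0], 0.0, None)
    return g / g.max()


def generate_motion(
    anatomy: LabeledSurfaceMesh,
    spec: CohortSpec | None = None,
    subject_seed: int = 0,
    regions: np.ndarray | None = None,
    rs_targets: dict | None = None,
    laef_pct: float | None = None,
    uac: UACField | None = None,
):
    """Deform an anatomy through one cardiac cycle.

    The motion is a per-vertex radial scaling about the chamber centre:
    region-specific amplitudes realize the requested regional reservoir
    strains, while a per-frame global homothety pins the capped volume
    curve to the LAEF-parameterized target -- so regional strain and
    global emptying are independently controllable.  Amplitudes are
    fixed-point calibrated against the measured ratio-of-sums strain.

    Returns ``(motion, truth)`` where truth holds the measured regional
    strain curves, reservoir strains, volume curve and LAV/LAEF.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng([int(spec.seed), int(subject_seed), 2])
    if regions is None:
        uac = uac or build_uac(anatomy)
        regions = assign_regions(anatomy, uac, spec.antra_radius_mm)
    tri_regs = triangle_regions(anatomy, regions)

    draws = None
    if rs_targets is None or laef_pct is None:
        draws = subject_draws(spec, subject_seed)
    rs_targets = rs_targets or draws["rs_targets"]
    laef_pct = laef_pct if laef_pct is not None else draws["laef_pct"]

    T = spec.frames_per_cycle
    t = np.arange(T) / T
    g = _cycle_envelope(t)

    ev = VolumeEvaluator(anatomy, DEFAULT_EXCLUDE)
    v0 = anatomy.vertices
    center = v0[anatomy.body_mask].mean(axis=0)
    rel = v0 - center

    v_min = float(ev(v0))
    if not 0 < laef_pct < 100:
        raise GeneratorError("LAEF must be in (0, 100)")
    v_max = v_min / (1.0 - laef_pct / 100.0)
    v_target = v_min + (v_max - v_min) * g

    # --- decoupling surface area from enclosed volume -----------------
    # A purely radial motion cannot realize arbitrary (regional strain,
    # LAEF) pairs: scaling by s multiplies areas by s^2 and volume by
    # s^3, and the isoperimetric inequality pins their ratio.  The
    # generator therefore drives two modes: smooth region-wise radial
    # amplitudes a_k carry the regional strain pattern, while the
    # baked-in wall corrugation deepens or flattens over the cycle,
    # changing surface area at nearly constant volume.  The corrugation
    # level at peak is solved so the volume-pinning homothety c(t)
    # stays near 1, after which the regional peak stretches are refined
    # against the measured ratio-of-sums strain.
    from .mesh import triangle_areas as _tri_areas

    tri = anatomy.triangles
    eta = np.zeros(anatomy.n_vertices)
    wpos = anatomy.landmarks.get("wrinkle_positive", np.empty(0, int))
    eta[wpos] = 1.0
    eta[(eta == 0) & (regions != "")] = -1.0
    w0 = spec.wrinkle_depth
    body_tris = tri_regs != ""

    def wrinkle_factor(vals):
        """Body-area multiplier A(e)/A(w0) for corrugation levels e."""
        out = []
        a_ref = None
        for e in vals:
            rho = (1.0 + e * eta) / (1.0 + w0 * eta)
            vv = center + rho[:, None] * rel
            out.append(_tri_areas(vv, tri)[body_tris].sum())
        a_ref = _tri_areas(v0, tri)[body_tris].sum()
        return np.asarray(out) / a_ref

    e_grid = np.linspace(0.0, max(2.2 * w0, 1e-6), 12)
    area_fac = wrinkle_factor(e_grid)          # monotone increasing in e
    phi_grid = np.sqrt(area_fac)               # linear-stretch equivalent

    target_stretch = np.array([np.sqrt(1.0 + rs_targets[r] / 100.0) for r in REGIONS])
    a_body = _tri_areas(v0, tri)
    w_reg = np.array([a_body[tri_regs == r].sum() for r in REGIONS])
    w_reg = w_reg / w_reg.sum()

    # every regional area curve is pinned to the SAME normalized
    # envelope, R_k(t) = 1 + (RS_k/100) g(t): curve shape then carries
    # no subject information (only the amplitudes do), which keeps the
    # strain principal components uninformative about LAV/LAEF-driven
    # fibrosis by construction.  Per frame, the corrugation level e(t)
    # is solved so the area targets and the volume target coexist, the
    # smooth stretches carry the regional pattern, and the homothety
    # c(t) pins the volume exactly.
    rs_vec = np.array([rs_targets[r] for r in REGIONS])
    R_t = 1.0 + (rs_vec[None, :] / 100.0) * g[:, None]       # (T, 6)
    Q_t = v_target / v_min                                   # (T,)
    m3_t = (w_reg[None, :] * R_t ** 1.5).sum(axis=1)
    W_t = np.clip((m3_t / Q_t) ** (2.0 / 3.0),
                  area_fac.min(), area_fac.max())
    s_t = np.sqrt(R_t / W_t[:, None])                        # (T, 6)
    frames = None
    for _ in range(5):
        # the homothety c(t) cancels any common-mode change of the
        # smooth stretches, so the corrugation level must absorb the
        # common-mode area error while s_t corrects the regional pattern
        e_t = np.interp(np.sqrt(W_t), phi_grid, e_grid)
        W_t = np.interp(e_t, e_grid, area_fac)
        rho_t = (1.0 + e_t[:, None] * eta[None, :]) / (1.0 + w0 * eta[None, :])

        off_body = spec.nonbody_motion_factor * (s_t.mean(axis=1) - 1.0)
        vert_s = 1.0 + np.tile(off_body[:, None], (1, anatomy.n_vertices))
        for i, r in enumerate(REGIONS):
            vert_s[:, regions == r] = s_t[:, [i]]
        scale = vert_s * rho_t
        raw = center + scale[:, :, None] * rel[None, :, :]
        v_raw = ev(raw)
        c = (v_target / v_raw) ** (1.0 / 3.0)
        frames = center + c[:, None, None] * (raw - center)

        # per-frame refinement against the measured ratio-of-sums areas
        curves = regional_strain_curves(MeshMotion(anatomy, frames, t), tri_regs)
        realized = np.stack(
            [1.0 + curves.regional[r] / 100.0 for r in REGIONS], axis=1
        )
        err = np.abs(realized - R_t).max()
        if err < 1e-3:
            break
        common = (w_reg[None, :] * (realized / R_t)).sum(axis=1)
        W_t = np.clip(W_t / common, area_fac.min(), area_fac.max())
        s_t = np.clip(s_t * np.sqrt(R_t / np.clip(realized, 0.25, None)),
                      0.5, 2.5)

    if spec.motion_jitter_mm > 0:
        jitter = rng.normal(0.0, spec.motion_jitter_mm, frames.shape)
        jitter[0] = 0.0
        frames = frames + jitter

    motion = MeshMotion(anatomy, frames, t)
    curves = regional_strain_curves(motion, tri_regs)
    vols = ev(frames)
    truth = {
        "rs_targets": dict(rs_targets),
        "regional_curves": {r: curves.regional[r].copy() for r in REGIONS},
        "global_curve": curves.global_curve.copy(),
        "rs_pct": {
            r: float(curves.regional[r].max() - curves.regional[r].min()) for r in REGIONS
        },
        "global_rs_pct": float(curves.global_curve.max() - curves.global_curve.min()),
        "volume_ml": vols.copy(),
        "lav_max_ml": float(vols.max()),
        "lav_min_ml": float(vols.min()),
        "laef_pct": float(100.0 * (vols.max() - vols.min()) / vols.max()),
    }
    return motion, truth


# ----------------------------------------------------------------------
# fibrosis
# ----------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_fibrosis(
    anatomy: LabeledSurfaceMesh,
    regions: np.ndarray,
    spec: CohortSpec | None = None,
    subject_seed: int = 0,
    lav_max_ml: float | None = None,
    laef_pct: float | None = None,
    rs_targets: dict | None = None,
    tri_regions_arr: np.ndarray | None = None,
    fibrosis_config: FibrosisConfig | None = None,
    targets_pct: dict | None = None,
):
    """Paint per-region fibrotic patches and emit LGE-like intensities.

    Severe status per region is Bernoulli with log-odds ``intercept +
    c_lav z(LAV) + c_laef z(LAEF) + region offset`` (plus the optional
    strain coupling term); the region's enhancement target is then
    drawn on the matching side of the severe cut and contiguous patches
    are grown vertex by vertex until the measured above-threshold area
    fraction matches the target within ~1 %.  Gaussian noise is added
    after the noise-free truth is measured.

    Returns ``(vertex_intensity, truth)``.
    """
    spec = spec or CohortSpec()
    cfg = fibrosis_config or FibrosisConfig()
    rng = np.random.default_rng([int(spec.seed), int(subject_seed), 3])
    draws = None
    if lav_max_ml is None or laef_pct is None:
        draws = subject_draws(spec, subject_seed)
    lav_max_ml = lav_max_ml if lav_max_ml is not None else draws["lav_max_ml"]
    laef_pct = laef_pct if laef_pct is not None else draws["laef_pct"]

    for r in REGIONS:
        if not np.any(regions == r):
            raise GeneratorError(f"region {r!r} missing from parcellation")
    tri_regs = tri_regions_arr if tri_regions_arr is not None else triangle_regions(
        anatomy, regions
    )

    z_lav = (lav_max_ml - spec.lav_mean) / spec.lav_sd
    z_laef = (laef_pct - spec.laef_mean) / spec.laef_sd

    severe_draw, targets = {}, {}
    if targets_pct is not None:
        cut = cfg.stage_bounds[2]
        targets = {r: float(targets_pct[r]) for r in REGIONS}
        severe_draw = {r: targets[r] > cut for r in REGIONS}
    for r in REGIONS if targets_pct is None else ():
        eta = (
            spec.severe_intercept
            + spec.link_coefficients["lav"] * z_lav
            + spec.link_coefficients["laef"] * z_laef
            + spec.region_offsets[r]
        )
        if spec.strain_fibrosis_coupling and rs_targets:
            z_rs = (rs_targets[r] - spec.regional_rs_mean) / spec.regional_rs_sd
            eta += spec.strain_fibrosis_coupling * (-z_rs)
        severe_draw[r] = bool(rng.random() < _sigmoid(eta))
        base = spec.fibrosis_region_base[r]
        cut = cfg.stage_bounds[2]
        if severe_draw[r]:
            targets[r] = _truncated_normal(rng, max(base, cut + 8), spec.fibrosis_sd,
                                           cut + 2.0, 95.0)
        else:
            targets[r] = _truncated_normal(rng, min(base, cut - 8), spec.fibrosis_sd,
                                           0.0, cut - 2.0)

    painted = _paint_patches(anatomy, regions, tri_regs, targets, cfg, rng)

    bp = spec.blood_pool_mean
    intensity = np.full(anatomy.n_vertices, spec.background_iir * bp)
    intensity[painted] = spec.enhanced_iir * bp

    iir_clean = intensity / bp
    fmap = regional_enhancement(anatomy, iir_clean, tri_regs, cfg)
    truth = {
        "target_pct": targets,
        "severe_drawn": severe_draw,
        "enhancement_pct": dict(fmap.enhancement_pct),
        "stage": dict(fmap.stage),
        "severe": dict(fmap.severe),
        "lav_max_ml": float(lav_max_ml),
        "laef_pct": float(laef_pct),
    }
    if spec.intensity_noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.intensity_noise_sd, len(intensity))
    return intensity, truth


def _paint_patches(anatomy, regions, tri_regs, targets, cfg, rng):
    """Grow contiguous painted-vertex patches to hit regional area targets."""
    areas = anatomy.triangle_areas()
    tri = anatomy.triangles
    n = anatomy.n_vertices

    neighbors = [[] for _ in range(n)]
    for a, b in anatomy.unique_edges():
        neighbors[a].append(int(b))
        neighbors[b].append(int(a))
    vert_tris = [[] for _ in range(n)]
    for m, t3 in enumerate(tri):
        for v in t3:
            vert_tris[v].append(m)

    painted = np.zeros(n, bool)

    def region_fraction(reg):
        mask = tri_regs == reg
        counts = painted[tri[mask]].sum(axis=1)
        return float(areas[mask][counts >= 2].sum() / areas[mask].sum())

    for reg in REGIONS:
        target = targets[reg] / 100.0
        rverts = np.where(regions == reg)[0]
        if target <= 0:
            continue
        n_patch = 1 + int(rng.integers(0, 2))
        seeds = rng.choice(rverts, size=min(n_patch, len(rverts)), replace=False)
        in_region = np.zeros(n, bool)
        in_region[rverts] = True

        order = []
        seen = np.zeros(n, bool)
        queues = [deque([int(s)]) for s in seeds]
        for s in seeds:
            seen[s] = True
        while any(queues):
            for q in queues:
                if not q:
                    continue
                v = q.popleft()
                order.append(v)
                for w in neighbors[v]:
                    if in_region[w] and not seen[w]:
                        seen[w] = True
                        q.append(w)

        best_err, best_k = abs(region_fraction(reg) - target), 0
        for k, v in enumerate(order, start=1):
            painted[v] = True
            err = abs(region_fraction(reg) - target)
            if err < best_err - 1e-12:
                best_err, best_k = err, k
            if region_fraction(reg) >= target and err > best_err:
                break
        painted[order] = False
        painted[order[:best_k]] = True

    # cross-region fix-up: boundary triangles let one region's paint
    # leak into a neighbour's count, so re-trim regions jointly until
    # every achieved fraction sits within the closure tolerance
    for _ in range(4):
        worst = 0.0
        for reg in REGIONS:
            target = targets[reg] / 100.0
            frac = region_fraction(reg)
            if abs(frac - target) <= 0.008:
                worst = max(worst, abs(frac - target))
                continue
            rverts = [v for v in np.where(regions == reg)[0]]
            if frac < target:
                frontier = [v for v in rverts
                            if not painted[v] and any(painted[w] for w in neighbors[v])]
                cand = frontier or [v for v in rverts if not painted[v]]
                for v in cand:
                    painted[v] = True
                    if region_fraction(reg) >= target:
                        break
            else:
                lit = [v for v in rverts if painted[v]]
                for v in reversed(lit):
                    painted[v] = False
                    if region_fraction(reg) <= target:
                        break
            worst = max(worst, abs(region_fraction(reg) - target))
        if worst <= 0.008:
            break
    return painted


# ----------------------------------------------------------------------
# whole subjects and cohorts
# ----------------------------------------------------------------------

def generate_subject(spec: CohortSpec, subject_index: int) -> SyntheticSubject:
    """Generate one complete subject: anatomy, motion, fibrosis, truth."""
    draws = subject_draws(spec, subject_index)
    v_min = draws["lav_max_ml"] * (1.0 - draws["laef_pct"] / 100.0)
    anatomy = generate_anatomy(spec, subject_index, target_volume_ml=v_min)
    uac = build_uac(anatomy)
    regions = assign_regions(anatomy, uac, spec.antra_radius_mm)
    tri_regs = triangle_regions(anatomy, regions)
    motion, motion_truth = generate_motion(
        anatomy, spec, subject_index, regions=regions,
        rs_targets=draws["rs_targets"], laef_pct=draws["laef_pct"],
    )
    intensity, fib_truth = generate_fibrosis(
        anatomy, regions, spec, subject_index,
        lav_max_ml=motion_truth["lav_max_ml"], laef_pct=motion_truth["laef_pct"],
        rs_targets=draws["rs_targets"], tri_regions_arr=tri_regs,
    )
    truth = {**motion_truth, **fib_truth}
    return SyntheticSubject(
        subject_id=f"{spec.cohort}{subject_index:03d}",
        anatomy=anatomy,
        uac=uac,
        regions=regions,
        tri_regions=tri_regs,
        motion=motion,
        vertex_intensity=intensity,
        blood_pool_mean=spec.blood_pool_mean,
        center=anatomy.vertices[anatomy.body_mask].mean(axis=0),
        truth=truth,
    )


def generate_cohort(spec: CohortSpec):
    """Generate all subjects of a cohort plus the tidy truth table.

    Returns ``(subjects, table)`` where the table has one row per
    (subject, region) with the measured truth.
    """
    subjects = [generate_subject(spec, i) for i in range(spec.n_subjects)]
    rows = []
    for s in subjects:
        for r in REGIONS:
            rows.append({
                "cohort": spec.cohort,
                "subject": s.subject_id,
                "region": r,
                "rs_pct": s.truth["rs_pct"][r],
                "enhancement_pct": s.truth["enhancement_pct"][r],
                "stage": s.truth["stage"][r],
                "severe": s.truth["severe"][r],
                "lav_max_ml": s.truth["lav_max_ml"],
                "laef_pct": s.truth["laef_pct"],
                "global_rs_pct": s.truth["global_rs_pct"],
            })
    return subjects, pd.DataFrame(rows)


# ----------------------------------------------------------------------
# voxelization
# ----------------------------------------------------------------------

def voxelize_intensity(
    subject: SyntheticSubject,
    voxel_size_mm: float = 1.5,
    wall_thickness_mm: float = 3.0,
    margin_mm: float = 6.0,
    background: float = 0.0,
):
    """Rasterize a subject's vertex intensities into a NIfTI volume.

    The anatomy is star-shaped about its centre by construction, so a
    voxel is classified by comparing its radius with the surface radius
    along its direction (nearest-vertex lookup): wall voxels take the
    nearest vertex's LGE intensity, cavity voxels the blood-pool mean,
    and exterior voxels the background value.
    """
    import nibabel as nib

    if voxel_size_mm <= 0:
        raise GeneratorError("voxel_size_mm must be positive")
    if voxel_size_mm > wall_thickness_mm:
        warnings.warn(
            "voxel size exceeds the wall thickness; the rasterized wall "
            "may be discontinuous", stacklevel=2
        )
    v = subject.anatomy.vertices
    c = subject.center
    lo = v.min(axis=0) - margin_mm
    hi = v.max(axis=0) + margin_mm
    shape = np.ceil((hi - lo) / voxel_size_mm).astype(int) + 1
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size_mm
    affine[:3, 3] = lo

    grid = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3) * voxel_size_mm + lo

    rel = grid - c
    r = np.linalg.norm(rel, axis=1)
    r_safe = np.where(r == 0, 1.0, r)
    dirs = rel / r_safe[:, None]

    vrel = v - c
    vr = np.linalg.norm(vrel, axis=1)
    tree = cKDTree(vrel / vr[:, None])
    _, nearest = tree.query(dirs)
    surf_r = vr[nearest]

    half = 0.5 * wall_thickness_mm
    data = np.full(len(grid), float(background))
    cavity = r < surf_r - half
    wall = np.abs(r - surf_r) <= half
    data[cavity] = subject.blood_pool_mean
    data[wall] = subject.vertex_intensity[nearest[wall]]
    data[r == 0] = subject.blood_pool_mean

    img = nib.Nifti1Image(data.reshape(shape).astype(np.float32), affine)
    return img
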