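"""Area strain, regional curves, volume curves, resampling, tracking."""

import numpy as np
import pytest
import trimesh as tm

from lastrain import (
    LabeledSurfaceMesh,
    MeshMotion,
    area_strain,
    regional_strain_curves,
    resample_curve,
    track_surfaces,
    triangle_regions,
    volume_curve,
)
from lastrain.strain import StrainError


def motion_from_scales(mesh, scales):
    frames = np.stack([mesh.vertices * s for s in scales])
    return MeshMotion(mesh, frames, np.arange(len(scales)) / len(scales))


@pytest.fixture(scope="module")
def sphere_mesh():
    s = tm.creation.icosphere(subdivisions=4, radius=20.0)
    return LabeledSurfaceMesh(
        np.asarray(s.vertices), np.asarray(s.faces),
        np.full(len(s.vertices), "body", dtype="U12"),
    )


class TestAreaStrain:
    def test_uniform_scaling_law(self, la_mesh):
        lam = 1.1
        motion = motion_from_scales(la_mesh, [1.0, lam, 1.0])
        strain = area_strain(motion)
        assert np.abs(strain[1] - 21.0).max() < 1e-9
        assert np.abs(strain[0]).max() == 0.0

    def test_rigid_motion_gives_zero_strain(self, la_mesh):
        theta = 1.1
        rot = np.array(
            [[1, 0, 0],
             [0, np.cos(theta), -np.sin(theta)],
             [0, np.sin(theta), np.cos(theta)]]
        )
        frames = np.stack([
            la_mesh.vertices,
            la_mesh.vertices @ rot.T + [3.0, -2.0, 7.0],
            la_mesh.vertices + 5.0,
        ])
        strain = area_strain(MeshMotion(la_mesh, frames, np.arange(3) / 3))
        assert np.abs(strain).max() < 1e-9

    def test_matches_direct_area_recomputation(self, la_mesh):
        rng = np.random.default_rng(4)
        frames = np.stack([
            la_mesh.vertices,
            la_mesh.vertices + rng.normal(0, 0.3, la_mesh.vertices.shape),
            la_mesh.vertices * 1.02,
        ])
        motion = MeshMotion(la_mesh, frames, np.arange(3) / 3)
        strain = area_strain(motion)
        a0 = la_mesh.triangle_areas()
        for t in range(3):
            at = la_mesh.triangle_areas(frames[t])
            np.testing.assert_array_equal(strain[t], 100.0 * (at - a0) / a0)

    def test_motion_contract_violations(self, la_mesh):
        with pytest.raises(StrainError, match="at least 3"):
            MeshMotion(la_mesh, np.stack([la_mesh.vertices] * 2), np.arange(2) / 2)
        with pytest.raises(StrainError, match="frame 0"):
            MeshMotion(
                la_mesh, np.stack([la_mesh.vertices + 1.0] * 3), np.arange(3) / 3
            )


class TestRegionalCurves:
    def test_uniform_motion_regional_equals_global(self, la_mesh, la_regions):
        tri_regs = triangle_regions(la_mesh, la_regions)
        motion = motion_from_scales(la_mesh, [1.0, 1.05, 1.02])
        curves = regional_strain_curves(motion, tri_regs)
        for reg, c in curves.regional.items():
            np.testing.assert_allclose(c, curves.global_curve, atol=1e-9)

    def test_ratio_of_sums_matches_manual_oracle(self, la_mesh, la_regions):
        tri_regs = triangle_regions(la_mesh, la_regions)
        rng = np.random.default_rng(9)
        frames = np.stack([
            la_mesh.vertices,
            la_mesh.vertices * (1 + rng.normal(0, 0.02, (la_mesh.n_vertices, 1))),
            la_mesh.vertices,
        ])
        motion = MeshMotion(la_mesh, frames, np.arange(3) / 3)
        curves = regional_strain_curves(motion, tri_regs)
        a0 = la_mesh.triangle_areas()
        a1 = la_mesh.triangle_areas(frames[1])
        for reg, c in curves.regional.items():
            mask = tri_regs == reg
            expected = 100.0 * (a1[mask].sum() - a0[mask].sum()) / a0[mask].sum()
            assert abs(c[1] - expected) < 1e-9

    def test_empty_region_raises(self, la_mesh, la_regions):
        tri_regs = triangle_regions(la_mesh, la_regions)
        tri_regs[tri_regs == "septal"] = "anterior"
        motion = motion_from_scales(la_mesh, [1.0, 1.1, 1.0])
        with pytest.raises(StrainError, match="septal"):
            regional_strain_curves(motion, tri_regs)

    def test_mean_of_elements_variant(self, la_mesh, la_regions):
        tri_regs = triangle_regions(la_mesh, la_regions)
        motion = motion_from_scales(la_mesh, [1.0, 1.1, 1.0])
        ratio = regional_strain_curves(motion, tri_regs, method="ratio_of_sums")
        mean = regional_strain_curves(motion, tri_regs, method="mean_of_elements")
        for reg in ratio.regional:  # identical under uniform scaling
            np.testing.assert_allclose(
                ratio.regional[reg], mean.regional[reg], atol=1e-9
            )


class TestVolumeCurve:
    def test_sphere_volume_matches_closed_form(self, sphere_mesh):
        radii = np.array([20.0, 24.0, 22.0])
        motion = motion_from_scales(sphere_mesh, radii / 20.0)
        vols, gf = volume_curve(motion, exclude=())
        expected = 4 / 3 * np.pi * radii ** 3 / 1000.0
        np.testing.assert_allclose(vols, expected, rtol=0.005)

    def test_laef_formula_exact(self, sphere_mesh):
        vols0, _ = volume_curve(motion_from_scales(sphere_mesh, [1.0, 1.0, 1.0]), exclude=())
        v0 = vols0[0]
        s_min = (40.0 / v0) ** (1 / 3)
        small = sphere_mesh.with_vertices(sphere_mesh.vertices * s_min)
        s_max = (100.0 / 40.0) ** (1 / 3)
        motion = motion_from_scales(small, [1.0, s_max, 1.0])
        _, gf = volume_curve(motion, exclude=())
        assert gf.lav_max_ml == pytest.approx(100.0, rel=1e-9)
        assert gf.lav_min_ml == pytest.approx(40.0, rel=1e-9)
        assert gf.laef_pct == pytest.approx(60.0, abs=1e-9)

    def test_constant_volume_gives_zero_laef(self, sphere_mesh):
        motion = motion_from_scales(sphere_mesh, [1.0, 1.0, 1.0])
        _, gf = volume_curve(motion, exclude=())
        assert gf.laef_pct == 0.0


class TestResample:
    def test_identity_on_own_grid(self):
        t = np.arange(10) / 10
        c = np.sin(2 * np.pi * t)
        np.testing.assert_allclose(resample_curve(c, t, 10), c, atol=1e-12)

    def test_linear_ramp_exact_when_downsampling(self):
        t = np.arange(40) / 40
        c = 3.0 * t
        out = resample_curve(c, t, 20)
        np.testing.assert_allclose(out, 3.0 * np.arange(20) / 20, atol=1e-12)

    def test_sine_error_below_linear_interpolation_bound(self):
        t = np.arange(50) / 50
        c = np.sin(2 * np.pi * t)
        out = resample_curve(c, t, 30)
        expected = np.sin(2 * np.pi * np.arange(30) / 30)
        bound = (2 * np.pi) ** 2 / 8 / 50 ** 2  # h^2 max|f''| / 8
        assert np.abs(out - expected).max() <= bound + 1e-12

    def test_input_validation(self):
        t = np.arange(5) / 5
        with pytest.raises(StrainError):
            resample_curve(np.zeros(5), t, 2)
        with pytest.raises(StrainError):
            resample_curve(np.zeros(2), t[:2], 10)
        with pytest.raises(StrainError, match="duplicate"):
            resample_curve(np.zeros(5), np.array([0, 0.1, 0.1, 0.3, 0.4]), 10)


class TestTracker:
    def test_identical_targets_give_zero_motion(self, la_mesh):
        targets = [la_mesh, la_mesh]
        motion = track_surfaces(la_mesh, targets)
        assert motion.n_frames == 3
        np.testing.assert_allclose(motion.frames[1], la_mesh.vertices, atol=1e-9)
        assert motion.residuals_mm.max() < 1e-9
        np.testing.assert_array_equal(
            motion.reference.triangles, la_mesh.triangles
        )

    def test_recovers_smooth_synthetic_motion(self):
        from lastrain.synthetic import CohortSpec, generate_motion, generate_anatomy
        from lastrain import build_uac, assign_regions

        spec = CohortSpec.preset(
            "AF", 1, seed=21, wrinkle_depth=0.0, motion_jitter_mm=0.0,
            frames_per_cycle=10,
        )
        anatomy = generate_anatomy(spec, 0, target_volume_ml=70.0)
        uac = build_uac(anatomy)
        regions = assign_regions(anatomy, uac)
        motion, truth = generate_motion(anatomy, spec, 0, regions=regions)
        targets = [anatomy.with_vertices(motion.frames[t]) for t in range(1, motion.n_frames)]
        tracked = track_surfaces(anatomy, targets, frame_times=motion.frame_times)
        tri_regs = triangle_regions(anatomy, regions)
        curves = regional_strain_curves(tracked, tri_regs)
        for reg, c in curves.regional.items():
            rs_true = truth["rs_pct"][reg]
            rs_tracked = float(c.max() - c.min())
            assert abs(rs_tracked - rs_true) / max(rs_true, 1.0) < 0.10
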