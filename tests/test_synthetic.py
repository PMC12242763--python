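"""Generator contracts: determinism, calibration, truth closure."""

import numpy as np
import pytest

from lastrain import (
    build_uac,
    assign_regions,
    enclosed_volume,
    generate_anatomy,
    generate_cohort,
    generate_fibrosis,
    generate_motion,
    triangle_regions,
    voxelize_intensity,
)
from lastrain.mesh import DEFAULT_EXCLUDE
from lastrain.parameterization import REGIONS
from lastrain.synthetic import CohortSpec, GeneratorError, generate_subject, subject_draws


@pytest.fixture(scope="module")
def healthy200_motion():
    """Motion truth for 200 healthy subjects (no fibrosis stage)."""
    spec = CohortSpec.preset("healthy", 200, seed=11)
    rows = []
    for i in range(spec.n_subjects):
        draws = subject_draws(spec, i)
        v_min = draws["lav_max_ml"] * (1 - draws["laef_pct"] / 100)
        anatomy = generate_anatomy(spec, i, target_volume_ml=v_min)
        uac = build_uac(anatomy)
        regions = assign_regions(anatomy, uac, spec.antra_radius_mm)
        _, truth = generate_motion(
            anatomy, spec, i, regions=regions,
            rs_targets=draws["rs_targets"], laef_pct=draws["laef_pct"],
        )
        rows.append(truth)
    return rows


class TestAnatomy:
    def test_same_seed_bitwise_identical(self):
        a = generate_anatomy(subject_seed=4, target_volume_ml=75.0)
        b = generate_anatomy(subject_seed=4, target_volume_ml=75.0)
        np.testing.assert_array_equal(a.vertices, b.vertices)
        np.testing.assert_array_equal(a.triangles, b.triangles)
        np.testing.assert_array_equal(a.vertex_labels, b.vertex_labels)

    def test_volume_targeting(self):
        mesh = generate_anatomy(subject_seed=2, target_volume_ml=80.0)
        assert enclosed_volume(mesh, DEFAULT_EXCLUDE) == pytest.approx(80.0, rel=0.02)

    def test_invariants_hold(self):
        mesh = generate_anatomy(subject_seed=3, target_volume_ml=60.0)
        mesh.validate()
        assert set(np.unique(mesh.vertex_labels)) >= {"body", "LSPV", "mitral_rim"}

    def test_invalid_target_raises(self):
        with pytest.raises(GeneratorError):
            generate_anatomy(subject_seed=0, target_volume_ml=-5.0)


class TestMotion:
    def test_pure_uniform_scaling_hits_scaling_law(self):
        # all modulation off: equal regional targets, matching LAEF, no
        # corrugation, rigid PV/LAA -> every element peaks at lam^2 - 1
        lam = 1.10
        rs = 100.0 * (lam ** 2 - 1.0)
        laef = 100.0 * (1.0 - lam ** -3)
        spec = CohortSpec.preset(
            "AF", 1, seed=5, wrinkle_depth=0.0, motion_jitter_mm=0.0,
            nonbody_motion_factor=1.0,
        )
        anatomy = generate_anatomy(spec, 0, target_volume_ml=70.0)
        uac = build_uac(anatomy)
        regions = assign_regions(anatomy, uac)
        motion, truth = generate_motion(
            anatomy, spec, 0, regions=regions,
            rs_targets={r: rs for r in REGIONS}, laef_pct=laef,
        )
        from lastrain import area_strain

        peak = area_strain(motion).max(axis=0)
        np.testing.assert_allclose(peak, rs, atol=0.05)

    def test_minimal_three_frame_sequence(self):
        spec = CohortSpec.preset("AF", 1, seed=6, frames_per_cycle=3)
        anatomy = generate_anatomy(spec, 0, target_volume_ml=70.0)
        motion, truth = generate_motion(anatomy, spec, 0)
        assert motion.n_frames == 3

    def test_healthy_pooled_rs_matches_cohort_mean(self, healthy200_motion):
        pooled = np.array(
            [t["rs_pct"][r] for t in healthy200_motion for r in REGIONS]
        )
        assert abs(pooled.mean() - 48.0) < 3.0

    def test_volume_curve_pinned_to_laef(self, healthy200_motion):
        for t in healthy200_motion[:50]:
            assert t["volume_ml"].min() > 0
            assert t["laef_pct"] == pytest.approx(
                100 * (t["lav_max_ml"] - t["lav_min_ml"]) / t["lav_max_ml"], abs=1e-9
            )


@pytest.fixture(scope="module")
def parcellated():
    spec = CohortSpec.preset("AF", 1, seed=8, intensity_noise_sd=0.0)
    anatomy = generate_anatomy(spec, 0, target_volume_ml=80.0)
    uac = build_uac(anatomy)
    regions = assign_regions(anatomy, uac)
    return spec, anatomy, regions


class TestFibrosis:

    def test_zero_targets_paint_nothing(self, parcellated):
        spec, anatomy, regions = parcellated
        intensity, truth = generate_fibrosis(
            anatomy, regions, spec, 0, lav_max_ml=100.0, laef_pct=30.0,
            targets_pct={r: 0.0 for r in REGIONS},
        )
        iir = intensity / spec.blood_pool_mean
        assert (iir < 1.2).all()
        assert all(v == 1 for v in truth["stage"].values())

    def test_painted_fraction_recovered_within_one_percent(self, parcellated):
        spec, anatomy, regions = parcellated
        targets = {r: 0.0 for r in REGIONS}
        targets["posterior"] = 50.0
        intensity, truth = generate_fibrosis(
            anatomy, regions, spec, 0, lav_max_ml=100.0, laef_pct=30.0,
            targets_pct=targets,
        )
        assert truth["enhancement_pct"]["posterior"] == pytest.approx(50.0, abs=1.0)

    def test_missing_region_raises(self, parcellated):
        spec, anatomy, regions = parcellated
        broken = regions.copy()
        broken[broken == "lateral"] = "posterior"
        with pytest.raises(GeneratorError, match="lateral"):
            generate_fibrosis(anatomy, broken, spec, 0, lav_max_ml=100.0, laef_pct=30.0)


class TestCohort:
    def test_af47_table_shape(self, af47):
        _, table = af47
        assert len(table) == 47 * 6
        assert set(table["region"]) == set(REGIONS)

    def test_different_seeds_differ(self):
        _, t1 = generate_cohort(CohortSpec.preset("AF", 2, seed=1, frames_per_cycle=6))
        _, t2 = generate_cohort(CohortSpec.preset("AF", 2, seed=2, frames_per_cycle=6))
        assert not t1["enhancement_pct"].equals(t2["enhancement_pct"])

    def test_healthy_severe_prevalence_below_cap(self, healthy_cohort):
        spec = CohortSpec.preset("healthy", 1)
        _, table = healthy_cohort
        assert table["severe"].mean() <= spec.healthy_severe_cap

    def test_af_regional_pattern_lateral_maximum(self, af47):
        from lastrain import regional_prevalence

        _, table = af47
        prev = regional_prevalence(table)
        assert prev.idxmax() == "lateral"

    def test_strain_decoupled_from_enhancement(self, af47, healthy_cohort):
        import pandas as pd

        t = pd.concat([af47[1], healthy_cohort[1]])
        # within-cohort correlations; > 200 subject-regions per cohort
        for _, grp in t.groupby("cohort"):
            r = np.corrcoef(grp["rs_pct"], grp["enhancement_pct"])[0, 1]
            assert abs(r) < 0.1

    def test_truth_closure_with_measurement_pipeline(self, af47):
        from lastrain.fibrosis import regional_enhancement
        from lastrain.strain import regional_strain_curves, volume_curve

        s = af47[0][0]
        fmap = regional_enhancement(
            s.anatomy,
            np.where(
                s.vertex_intensity / s.blood_pool_mean > 0, s.vertex_intensity, 0
            ) / s.blood_pool_mean,
            s.tri_regions,
        )
        curves = regional_strain_curves(s.motion, s.tri_regions)
        vols, gf = volume_curve(s.motion)
        np.testing.assert_allclose(vols, s.truth["volume_ml"], rtol=0.01)
        for r in REGIONS:
            np.testing.assert_allclose(
                curves.regional[r], s.truth["regional_curves"][r], atol=1e-9
            )


@pytest.fixture(scope="module")
def subject():
    spec = CohortSpec.preset("AF", 1, seed=12, intensity_noise_sd=0.0,
                             motion_jitter_mm=0.0)
    return generate_subject(spec, 0)


class TestVoxelization:

    def test_round_trip_correlation(self, subject):
        from lastrain import project_image_to_surface

        img = voxelize_intensity(subject, voxel_size_mm=1.5)
        projected = project_image_to_surface(img, subject.anatomy, depth_mm=3.0)
        r = np.corrcoef(projected, subject.vertex_intensity)[0, 1]
        assert r > 0.95

    def test_cavity_mean_matches_blood_pool(self, subject):
        from lastrain import estimate_blood_pool_mean

        img = voxelize_intensity(subject, voxel_size_mm=1.5)
        est = estimate_blood_pool_mean(img, subject.anatomy)
        assert est == pytest.approx(subject.blood_pool_mean, rel=0.02)

    def test_uniform_intensity_rasterizes_uniformly(self, subject):
        s2 = subject
        s2.vertex_intensity = np.full(s2.anatomy.n_vertices, 90.0)
        img = voxelize_intensity(s2, voxel_size_mm=2.0)
        data = np.asarray(img.get_fdata())
        wall = (data != 0) & (data != s2.blood_pool_mean)
        assert np.allclose(data[wall], 90.0)

    def test_large_voxels_warn(self, subject):
        with pytest.warns(UserWarning, match="wall"):
            voxelize_intensity(subject, voxel_size_mm=5.0)
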