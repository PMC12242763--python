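"""Feature extraction and the classification harness."""

import numpy as np
import pandas as pd
import pytest

from lastrain.features import (
    CURVE_GRID,
    ClassificationReport,
    CohortNormalization,
    FeatureError,
    StrainPCA,
    SubjectRecord,
    _CURVE_COLS,
    build_feature_table,
    crossval_classify,
    evaluate_external,
    feature_combination_sweep,
    peak_strain_rate,
    permutation_pvalue,
    permute_subject_labels,
    regional_prevalence,
    reservoir_strain,
    split_holdout,
    zscore,
)
from lastrain.parameterization import REGIONS


def synthetic_table(n_subjects=40, seed=0, signal=None, prevalence=0.4):
    """Minimal feature table with controllable label-feature link.

    ``signal``: None for pure noise, or a float giving the separation
    (in SDs) of the ``rs_pct`` feature between classes.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for r in REGIONS:
            severe = bool(rng.random() < prevalence)
            x = rng.normal(0.0, 1.0)
            if signal is not None:
                x += signal * severe
            curve = np.sin(2 * np.pi * np.arange(CURVE_GRID) / CURVE_GRID)
            curve = curve * rng.normal(1.0, 0.3) + rng.normal(0, 0.05, CURVE_GRID)
            row = {
                "subject": f"S{i:03d}", "region": r, "rs_pct": x,
                "strain_rate_pct_per_cycle": rng.normal(),
                "global_rs_pct": rng.normal(), "lav_max_ml": rng.normal(),
                "laef_pct": rng.normal(), "enhancement_pct": rng.uniform(0, 60),
                "severe": severe,
            }
            row.update({c: v for c, v in zip(_CURVE_COLS, curve)})
            rows.append(row)
    return pd.DataFrame(rows)


class TestCurveFeatures:
    def test_reservoir_strain_is_amplitude(self):
        assert reservoir_strain(np.array([0.0, 30.0, 0.0])) == 30.0
        assert reservoir_strain(np.zeros(10)) == 0.0
        rng = np.random.default_rng(2)
        c = rng.normal(size=50)
        assert reservoir_strain(c) == max(c) - min(c)  # exhaustive-scan oracle
        with pytest.raises(FeatureError):
            reservoir_strain(np.array([1.0, 2.0]))

    def test_peak_strain_rate_ramp_and_constant(self):
        t = np.arange(20) / 20
        assert peak_strain_rate(4.0 * t, t) == pytest.approx(4.0)
        assert peak_strain_rate(np.full(20, 3.0), t) == pytest.approx(0.0, abs=1e-12)

    def test_peak_strain_rate_sine_near_analytic(self):
        t = np.arange(60) / 60
        c = np.sin(2 * np.pi * t)
        peak = peak_strain_rate(c, t)
        assert peak == pytest.approx(2 * np.pi, rel=0.01)

    def test_duplicate_times_raise(self):
        with pytest.raises(FeatureError, match="duplicate"):
            peak_strain_rate(np.zeros(4), np.array([0.0, 0.1, 0.1, 0.3]))


class TestStrainPCA:
    def test_two_factor_family_recovered(self):
        rng = np.random.default_rng(5)
        grid = np.arange(30) / 30
        b1 = np.exp(-0.5 * ((grid - 0.3) / 0.08) ** 2)
        b2 = np.exp(-0.5 * ((grid - 0.7) / 0.08) ** 2)
        # distinct factor variances keep the eigenvalues separated, so
        # the components align with the generating bumps
        a = 3.0 * rng.normal(size=300)
        b = rng.normal(size=300)
        curves = a[:, None] * b1 + b[:, None] * b2 + rng.normal(0, 1e-4, (300, 30))
        pca = StrainPCA(2).fit(curves)
        assert pca.explained_variance_ratio_[:2].sum() > 0.99
        scores = pca.transform(curves)
        corr = np.abs(np.corrcoef(np.c_[scores, a, b].T))
        assert max(corr[0, 2], corr[0, 3]) > 0.99
        assert max(corr[1, 2], corr[1, 3]) > 0.99

    def test_orthonormal_loadings_and_zero_mean_score(self):
        rng = np.random.default_rng(6)
        curves = rng.normal(size=(50, 30))
        pca = StrainPCA(2).fit(curves)
        gram = pca.components_ @ pca.components_.T
        np.testing.assert_allclose(gram, np.eye(2), atol=1e-9)
        np.testing.assert_allclose(
            pca.transform(pca.mean_[None, :]), 0.0, atol=1e-9
        )

    def test_identical_curves_raise(self):
        with pytest.raises(FeatureError, match="identical"):
            StrainPCA(2).fit(np.ones((10, 30)))


class TestZScore:
    def test_cohort_arithmetic_example(self):
        norm = CohortNormalization(mu={"posterior": 48.0}, sd={"posterior": 33.2})
        z = float(zscore(19.5, norm, "posterior"))
        assert z == pytest.approx(-0.8584, abs=5e-5)
        assert float(zscore(48.0, norm, "posterior")) == 0.0

    def test_healthy_cohort_self_normalizes(self, healthy_cohort):
        _, table = healthy_cohort
        norm = CohortNormalization.from_table(table, "rs_pct")
        z = np.array([
            float(zscore(x, norm, r)) for x, r in zip(table["rs_pct"], table["region"])
        ])
        zt = table.assign(z=z)
        for _, grp in zt.groupby("region"):
            assert abs(grp["z"].mean()) < 1e-9
            assert abs(grp["z"].std(ddof=1) - 1.0) < 1e-9

    def test_missing_region_raises(self):
        with pytest.raises(FeatureError):
            zscore(1.0, CohortNormalization(), "posterior")


class TestFeatureTable:
    def test_shape_and_join_contracts(self, af47, af47_features):
        subjects, truth = af47
        table = af47_features
        assert len(table) == 282
        for _, grp in table.groupby("subject"):
            assert len(grp) == 6
            for col in ("global_rs_pct", "lav_max_ml", "laef_pct"):
                assert grp[col].nunique() == 1
        merged = table.merge(truth, on=["subject", "region"], suffixes=("", "_t"))
        assert (merged["severe"] == merged["severe_t"]).all()

    def test_missing_region_errors_with_name(self):
        rec = SubjectRecord(
            subject_id="X", regional_curves={"posterior": np.zeros(30)},
            frame_times=np.arange(30) / 30, global_curve=np.zeros(30),
            lav_max_ml=80.0, laef_pct=40.0, severe={}, enhancement_pct={},
        )
        with pytest.raises(FeatureError, match="X"):
            build_feature_table([rec])


class TestCrossval:
    def test_perfect_feature_perfect_metrics(self):
        table = synthetic_table(40, seed=1, signal=50.0)
        rep = crossval_classify(table, ("rs",), model_spec="rf", seed=0)
        assert rep.mean_accuracy_pct == 100.0
        assert rep.mean_auc == 1.0

    def test_null_feature_near_chance(self):
        table = synthetic_table(47, seed=2, signal=None)
        rep = crossval_classify(table, ("rs",), model_spec="logreg", seed=0)
        base = max(table["severe"].mean(), 1 - table["severe"].mean()) * 100
        n = len(table) / 5
        band = 100 * 2 * np.sqrt(0.25 / n)  # ~binomial 95% band per fold
        assert rep.mean_accuracy_pct < base + band

    def test_deterministic_under_seed(self, af47_features):
        a = crossval_classify(af47_features, ("region", "lav", "laef"), seed=3)
        b = crossval_classify(af47_features, ("region", "lav", "laef"), seed=3)
        assert a.to_dict() == b.to_dict()

    def test_single_class_errors(self):
        table = synthetic_table(10, seed=3)
        table["severe"] = True
        with pytest.raises(FeatureError, match="class"):
            crossval_classify(table, ("rs",))

    def test_k_validation(self, af47_features):
        with pytest.raises(FeatureError):
            crossval_classify(af47_features, ("rs",), k=1)

    def test_ungrouped_reduces_to_stratified_kfold_oracle(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import accuracy_score
        from sklearn.model_selection import StratifiedKFold
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        table = synthetic_table(30, seed=4, signal=1.0)
        rep = crossval_classify(
            table, ("rs",), model_spec="logreg", group_by_subject=False, seed=7
        )
        X = table[["rs_pct"]].to_numpy()
        y = table["severe"].to_numpy(bool)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=7)
        expected = []
        for tr, te in skf.split(table, y):
            m = make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
            m.fit(X[tr], y[tr])
            expected.append(100 * accuracy_score(y[te], m.predict(X[te])))
        np.testing.assert_allclose(rep.fold_accuracy_pct, expected, atol=1e-9)

    def test_fold_transformers_fit_on_training_block_only(self):
        # leakage sentinel: corrupt the held-out curves and labels after
        # the split; neither the PCA loadings nor the z-normalization
        # may change, and test scores must be projections onto the
        # train-fit loadings
        from lastrain.features import _FoldDesign

        rng = np.random.default_rng(8)
        table = synthetic_table(40, seed=5, signal=None)
        tr, te = split_holdout(table, 0.3, seed=0)
        design = _FoldDesign(("pc1", "pc2", "z_rs")).fit(tr)
        comps = design._pca.components_.copy()
        mu = dict(design._z.mu)

        te = te.copy()
        te[_CURVE_COLS] = rng.normal(0, 100, (len(te), CURVE_GRID))
        te["severe"] = True
        X = design.transform(te)
        np.testing.assert_array_equal(design._pca.components_, comps)
        assert design._z.mu == mu
        expected = (te[_CURVE_COLS].to_numpy() - design._pca.mean_) @ comps.T
        np.testing.assert_allclose(X[:, 0], expected[:, 0], atol=1e-9)


class TestPermutation:
    def test_block_permutation_preserves_subject_vectors(self):
        table = synthetic_table(12, seed=6)
        rng = np.random.default_rng(0)
        shuffled = permute_subject_labels(table, rng)
        orig = {
            s: tuple(g.sort_values("region")["severe"]) for s, g in table.groupby("subject")
        }
        new = {
            s: tuple(g.sort_values("region")["severe"]) for s, g in shuffled.groupby("subject")
        }
        assert sorted(orig.values()) == sorted(new.values())

    def test_perfect_separation_gives_minimal_p(self):
        table = synthetic_table(25, seed=7, signal=50.0)
        rep = permutation_pvalue(table, ("rs",), model_spec="logreg", n_perm=99, seed=0)
        assert rep.p_accuracy == pytest.approx(1 / 100)
        assert rep.p_auc == pytest.approx(1 / 100)

    def test_constant_feature_gives_p_one_for_auc(self):
        table = synthetic_table(20, seed=8)
        table["rs_pct"] = 1.0
        rep = permutation_pvalue(table, ("rs",), model_spec="logreg", n_perm=99, seed=0)
        assert rep.p_auc == 1.0

    def test_minimum_permutations_enforced(self):
        table = synthetic_table(10, seed=9)
        with pytest.raises(FeatureError):
            permutation_pvalue(table, ("rs",), n_perm=10)


class TestSweepAndExternal:
    def test_sweep_counts(self):
        table = synthetic_table(25, seed=10, signal=1.0)
        reports = feature_combination_sweep(
            table, ["rs", "lav", "laef"], model_spec="logreg", seed=0
        )
        # 3 singletons + 3 pairs + designated triple
        assert len(reports) == 7
        assert "region+lav+laef" in reports

    def test_external_same_table_is_resubstitution(self):
        table = synthetic_table(25, seed=11, signal=3.0)
        res = evaluate_external(table, table, ("rs",), model_spec="logreg")
        assert res["n_test"] == len(table)
        assert res["accuracy_pct"] > 80.0

    def test_external_column_mismatch_raises(self):
        table = synthetic_table(10, seed=12)
        other = table.drop(columns=["rs_pct"])
        with pytest.raises(FeatureError):
            evaluate_external(table, other, ("rs",))


class TestHoldoutProtocol:
    def test_holdout_and_cv_are_grouped_and_reported(self):
        from lastrain.features import holdout_evaluation, split_holdout

        table = synthetic_table(40, seed=15, signal=3.0)
        res = holdout_evaluation(table, ("rs",), model_spec="logreg", seed=2)
        assert res["cv"]["mean_accuracy_pct"] > 70.0
        assert res["holdout"]["accuracy_pct"] > 70.0
        assert res["roc_points"] is not None and len(res["roc_points"]) >= 2
        # no subject may straddle the split
        tr, te = split_holdout(table, 0.2, seed=2)
        assert not set(tr["subject"]) & set(te["subject"])
        assert res["holdout"]["n_test"] == len(te)


class TestPrevalence:
    def test_all_severe_and_tally_oracle(self):
        table = synthetic_table(15, seed=13)
        table["severe"] = True
        prev = regional_prevalence(table)
        assert (prev == 100.0).all()
        table2 = synthetic_table(15, seed=14)
        prev2 = regional_prevalence(table2)
        for r in REGIONS:
            sub = table2[table2["region"] == r]
            assert prev2[r] == pytest.approx(100.0 * sub["severe"].mean())

    def test_empty_errors(self):
        with pytest.raises(FeatureError):
            regional_prevalence(pd.DataFrame(columns=["region", "severe"]))
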