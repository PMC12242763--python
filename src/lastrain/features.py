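"""Strain-derived features and the severe-fibrosis classification harness.

Per (subject, region) the feature table carries: regional area
reservoir strain (curve amplitude, max - min), peak area strain rate,
the first two principal-component scores of the resampled strain
curves, optional fibre reservoir strain, and the subject's global
reservoir strain, LAV and LAEF; the label is the region's severe-
fibrosis flag (> 30 % enhancement).

The harness runs grouped, stratified 5-fold cross-validation with a
pluggable model (random forest by default), reports mean +- SD fold
accuracy and ROC AUC, and attaches permutation p-values computed by
reshuffling whole-subject label blocks.  Anything fit from data (PCA
loadings, z-normalizations, the model) is fit on training folds only.

Z-scores against a healthy reference cohort follow
``z = (x - mu_healthy) / sigma_healthy`` per region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import GroupShuffleSplit, StratifiedGroupKFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .parameterization import REGIONS
from .strain import resample_curve

CURVE_GRID = 30
_CURVE_COLS = [f"curve_{k:02d}" for k in range(CURVE_GRID)]

#: feature-set name -> table column for plain column features
FEATURE_COLUMNS = {
    "rs": "rs_pct",
    "strain_rate": "strain_rate_pct_per_cycle",
    "fibre_rs": "fibre_rs_pct",
    "global_rs": "global_rs_pct",
    "lav": "lav_max_ml",
    "laef": "laef_pct",
}


class FeatureError(ValueError):
    pass


# ----------------------------------------------------------------------
# curve-level features
# ----------------------------------------------------------------------

def reservoir_strain(curve: np.ndarray) -> float:
    """Reservoir strain: the amplitude (max - min) of a strain curve, %."""
    curve = np.asarray(curve, float)
    if curve.size < 3:
        raise FeatureError("need at least 3 frames")
    return float(curve.max() - curve.min())


def peak_strain_rate(curve: np.ndarray, frame_times: np.ndarray) -> float:
    """Peak absolute strain rate over the cycle, %/cycle.

    Central differences in the interior, one-sided at the cycle ends.
    """
    curve = np.asarray(curve, float)
    t = np.asarray(frame_times, float)
    if curve.size < 3:
        raise FeatureError("need at least 3 frames")
    if len(np.unique(t)) != len(t):
        raise FeatureError("duplicate frame times")
    return float(np.abs(np.gradient(curve, t)).max())


class StrainPCA:
    """PCA of resampled strain curves with train-only fitting.

    Components are mean-centered and orthonormal, ordered by explained
    variance; scores of new curves are projections onto the loadings.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components
        self._pca = None

    def fit(self, curves: np.ndarray) -> "StrainPCA":
        curves = np.asarray(curves, float)
        if curves.ndim != 2 or len(curves) < 2:
            raise FeatureError("need a (n_curves, n_frames) matrix with n >= 2")
        if np.allclose(curves.var(axis=0).sum(), 0.0):
            raise FeatureError("strain curves are identical: PCA is undefined")
        self._pca = PCA(n_components=min(self.n_components, *curves.shape),
                        svd_solver="full", random_state=0)
        self._pca.fit(curves)
        return self

    @property
    def mean_(self):
        return self._pca.mean_

    @property
    def components_(self):
        return self._pca.components_

    @property
    def explained_variance_ratio_(self):
        return self._pca.explained_variance_ratio_

    def transform(self, curves: np.ndarray) -> np.ndarray:
        if self._pca is None:
            raise FeatureError("fit before transform")
        return self._pca.transform(np.asarray(curves, float))


# ----------------------------------------------------------------------
# healthy-reference normalization
# ----------------------------------------------------------------------

@dataclass
class CohortNormalization:
    """Per-region healthy-cohort mean and SD of a feature (default RS)."""

    mu: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    @classmethod
    def from_table(cls, table: pd.DataFrame, column: str = "rs_pct") -> "CohortNormalization":
        out = cls()
        for region, grp in table.groupby("region"):
            sd = float(grp[column].std(ddof=1))
            if not sd > 0:
                raise FeatureError(f"zero SD for region {region!r}")
            out.mu[region] = float(grp[column].mean())
            out.sd[region] = sd
        return out


def zscore(x, norm: CohortNormalization, region: str):
    """Z-score against the healthy reference: (x - mu) / sigma for the region."""
    if region not in norm.mu:
        raise FeatureError(f"region {region!r} missing from normalization")
    return (np.asarray(x, float) - norm.mu[region]) / norm.sd[region]


# ----------------------------------------------------------------------
# the feature table
# ----------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """Analysis outputs of one subject, ready for feature extraction."""

    subject_id: str
    regional_curves: dict           # region -> (T,) area strain %
    frame_times: np.ndarray
    global_curve: np.ndarray
    lav_max_ml: float
    laef_pct: float
    severe: dict                    # region -> bool
    enhancement_pct: dict
    fibre_rs: dict | None = None    # region -> %


def build_feature_table(
    records: list,
    normalization: CohortNormalization | None = None,
    n_grid: int = CURVE_GRID,
) -> pd.DataFrame:
    """Join per-subject outputs into the (subject, region) feature table.

    Each row carries the regional features, the subject's global
    features repeated across its six rows, the severe label, and the
    resampled strain curve (columns ``curve_00..``) so that
    fold-hygienic PCA can be refit inside cross-validation.  Table-wide
    ``pc1``/``pc2`` scores are included for reporting.
    """
    rows = []
    for rec in records:
        missing = [r for r in REGIONS if r not in rec.regional_curves or r not in rec.severe]
        if missing:
            raise FeatureError(
                f"subject {rec.subject_id}: missing region outputs {missing}"
            )
        g_rs = reservoir_strain(rec.global_curve)
        for region in REGIONS:
            curve = np.asarray(rec.regional_curves[region], float)
            res = resample_curve(curve, rec.frame_times, n_grid)
            row = {
                "subject": rec.subject_id,
                "region": region,
                "rs_pct": reservoir_strain(curve),
                "strain_rate_pct_per_cycle": peak_strain_rate(curve, rec.frame_times),
                "global_rs_pct": g_rs,
                "lav_max_ml": rec.lav_max_ml,
                "laef_pct": rec.laef_pct,
                "enhancement_pct": rec.enhancement_pct[region],
                "severe": bool(rec.severe[region]),
            }
            if rec.fibre_rs is not None:
                row["fibre_rs_pct"] = rec.fibre_rs[region]
            for k in range(n_grid):
                row[f"curve_{k:02d}"] = res[k]
            rows.append(row)
    table = pd.DataFrame(rows)

    pca = StrainPCA(2).fit(table[_CURVE_COLS[:n_grid]].to_numpy())
    scores = pca.transform(table[_CURVE_COLS[:n_grid]].to_numpy())
    table["pc1"] = scores[:, 0]
    table["pc2"] = scores[:, 1]
    if normalization is not None:
        table["z_rs"] = [
            float(zscore(x, normalization, r))
            for x, r in zip(table["rs_pct"], table["region"])
        ]
    return table


# ----------------------------------------------------------------------
# fold-hygienic design matrices
# ----------------------------------------------------------------------

class _FoldDesign:
    """Feature encoder fit on a training block only."""

    def __init__(self, feature_set):
        self.feature_set = list(feature_set)
        self._pca = None
        self._z = None

    def fit(self, train: pd.DataFrame) -> "_FoldDesign":
        if "pc1" in self.feature_set or "pc2" in self.feature_set:
            self._pca = StrainPCA(2).fit(train[_CURVE_COLS].to_numpy())
        if "z_rs" in self.feature_set:
            self._z = CohortNormalization.from_table(train, "rs_pct")
        return self

    def transform(self, block: pd.DataFrame) -> np.ndarray:
        cols = []
        scores = None
        if self._pca is not None:
            scores = self._pca.transform(block[_CURVE_COLS].to_numpy())
        for f in self.feature_set:
            if f == "region":
                onehot = np.column_stack(
                    [(block["region"] == r).to_numpy(float) for r in REGIONS]
                )
                cols.append(onehot)
            elif f in ("pc1", "pc2"):
                cols.append(scores[:, [0 if f == "pc1" else 1]])
            elif f == "z_rs":
                z = np.array([
                    float(zscore(x, self._z, r))
                    for x, r in zip(block["rs_pct"], block["region"])
                ])
                cols.append(z[:, None])
            elif f in FEATURE_COLUMNS:
                cols.append(block[[FEATURE_COLUMNS[f]]].to_numpy(float))
            else:
                cols.append(block[[f]].to_numpy(float))
        return np.hstack(cols)


def _make_model(model_spec, seed: int):
    if isinstance(model_spec, str):
        model_spec = {"kind": model_spec}
    spec = dict(model_spec)
    kind = spec.pop("kind", "rf")
    if kind == "rf":
        return RandomForestClassifier(
            n_estimators=spec.pop("n_estimators", 200), random_state=seed, **spec
        )
    if kind == "logreg":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, **spec)
        )
    if kind == "gboost":
        return GradientBoostingClassifier(random_state=seed, **spec)
    raise FeatureError(f"unknown model kind {kind!r}")


# ----------------------------------------------------------------------
# cross-validated classification
# ----------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """Fold metrics for one feature set."""

    feature_set: tuple
    fold_accuracy_pct: list
    fold_auc: list
    seed: int
    model: str
    p_accuracy: float | None = None
    p_auc: float | None = None
    n_permutations: int = 0

    @property
    def mean_accuracy_pct(self):
        return float(np.mean(self.fold_accuracy_pct))

    @property
    def sd_accuracy_pct(self):
        return float(np.std(self.fold_accuracy_pct, ddof=1))

    @property
    def mean_auc(self):
        return float(np.mean(self.fold_auc))

    @property
    def sd_auc(self):
        return float(np.std(self.fold_auc, ddof=1))

    def to_dict(self) -> dict:
        return {
            "feature_set": list(self.feature_set),
            "model": self.model,
            "seed": self.seed,
            "fold_accuracy_pct": [float(a) for a in self.fold_accuracy_pct],
            "fold_auc": [float(a) for a in self.fold_auc],
            "mean_accuracy_pct": self.mean_accuracy_pct,
            "sd_accuracy_pct": self.sd_accuracy_pct,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "p_accuracy": self.p_accuracy,
            "p_auc": self.p_auc,
            "n_permutations": self.n_permutations,
        }


def _predict_scores(model, X):
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def crossval_classify(
    table: pd.DataFrame,
    feature_set,
    model_spec="rf",
    k: int = 5,
    group_by_subject: bool = True,
    seed: int = 0,
) -> ClassificationReport:
    """Grouped, stratified k-fold CV of severe-fibrosis classification.

    All six regions of a subject share a fold (grouping prevents
    leakage through the subject-level global features); folds are
    stratified by the severe label.  Returns per-fold accuracy (%) and
    ROC AUC.
    """
    y = table["severe"].to_numpy(bool)
    if y.all() or not y.any():
        raise FeatureError("both classes must be present")
    if k < 2:
        raise FeatureError("k must be >= 2")
    # keep only the columns the feature set needs: fold slicing of the
    # wide curve block dominates runtime in permutation loops otherwise
    need = sorted(set(_required_columns(feature_set)) | {"subject", "region"})
    table = table[[c for c in need if c in table.columns]]
    groups = table["subject"].to_numpy()
    if group_by_subject:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(table, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(table, y)

    accs, aucs = [], []
    for tr, te in splits:
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise FeatureError(
                "a fold contains a single class; change the stratification seed"
            )
        design = _FoldDesign(feature_set).fit(table.iloc[tr])
        Xtr = design.transform(table.iloc[tr])
        Xte = design.transform(table.iloc[te])
        model = _make_model(model_spec, seed)
        model.fit(Xtr, y[tr])
        accs.append(100.0 * accuracy_score(y[te], model.predict(Xte)))
        aucs.append(roc_auc_score(y[te], _predict_scores(model, Xte)))
    return ClassificationReport(
        feature_set=tuple(feature_set),
        fold_accuracy_pct=accs,
        fold_auc=aucs,
        seed=seed,
        model=str(model_spec),
    )


def permute_subject_labels(table: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Reassign whole-subject severe-label blocks across subjects.

    Each subject receives another subject's region-aligned label
    vector, preserving the within-subject label structure while
    severing any feature-label association.
    """
    sub_codes, subjects = pd.factorize(table["subject"])
    perm = rng.permutation(len(subjects))
    reg_order = {r: k for k, r in enumerate(REGIONS)}
    reg_codes = np.array([reg_order[r] for r in table["region"]])
    grid = np.zeros((len(subjects), len(REGIONS)), dtype=bool)
    grid[sub_codes, reg_codes] = table["severe"].to_numpy(bool)
    out = table.copy()
    out["severe"] = grid[perm[sub_codes], reg_codes]
    return out


def permutation_pvalue(
    table: pd.DataFrame,
    feature_set,
    model_spec="rf",
    n_perm: int = 1000,
    k: int = 5,
    seed: int = 0,
) -> ClassificationReport:
    """Permutation significance of the cross-validated metrics.

    ``p = (1 + #{permuted >= observed}) / (n_perm + 1)`` for mean fold
    accuracy and mean fold AUC separately; the add-one convention keeps
    p strictly positive.
    """
    if n_perm < 99:
        raise FeatureError("use at least 99 permutations")
    report = crossval_classify(table, feature_set, model_spec, k=k, seed=seed)
    rng = np.random.default_rng(seed)
    ge_acc = ge_auc = 0
    for _ in range(n_perm):
        shuffled = permute_subject_labels(table, rng)
        y = shuffled["severe"]
        if y.all() or not y.any():
            ge_acc += 1
            ge_auc += 1
            continue
        try:
            r = crossval_classify(shuffled, feature_set, model_spec, k=k, seed=seed)
        except FeatureError:
            continue
        ge_acc += r.mean_accuracy_pct >= report.mean_accuracy_pct
        ge_auc += r.mean_auc >= report.mean_auc
    report.p_accuracy = (1.0 + ge_acc) / (n_perm + 1.0)
    report.p_auc = (1.0 + ge_auc) / (n_perm + 1.0)
    report.n_permutations = n_perm
    return report


def feature_combination_sweep(
    table: pd.DataFrame,
    base_features,
    model_spec="rf",
    k: int = 5,
    seed: int = 0,
    triple=("region", "lav", "laef"),
) -> dict:
    """All singleton and pairwise feature combinations, plus the
    designated (region, LAV, LAEF) triple."""
    base = list(base_features)
    if len(base) < 2:
        raise FeatureError("need at least two base features to sweep")
    combos = [(f,) for f in base]
    combos += [(a, b) for i, a in enumerate(base) for b in base[i + 1:]]
    if triple:
        combos.append(tuple(triple))
    return {
        "+".join(c): crossval_classify(table, c, model_spec, k=k, seed=seed)
        for c in combos
    }


def evaluate_external(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    feature_set,
    model_spec="rf",
    seed: int = 0,
) -> dict:
    """Fit on all of one cohort, evaluate once on another (no refitting)."""
    need = set(_required_columns(feature_set))
    missing = need - set(test_table.columns)
    if missing or (need - set(train_table.columns)):
        raise FeatureError(f"feature columns missing from a table: {sorted(missing)}")
    design = _FoldDesign(feature_set).fit(train_table)
    model = _make_model(model_spec, seed)
    y_tr = train_table["severe"].to_numpy(bool)
    model.fit(design.transform(train_table), y_tr)
    y_te = test_table["severe"].to_numpy(bool)
    X_te = design.transform(test_table)
    auc = None
    if len(np.unique(y_te)) == 2:
        auc = float(roc_auc_score(y_te, _predict_scores(model, X_te)))
    return {
        "accuracy_pct": float(100.0 * accuracy_score(y_te, model.predict(X_te))),
        "auc": auc,
        "n_test": int(len(test_table)),
    }


def _required_columns(feature_set):
    cols = ["severe", "region"]
    for f in feature_set:
        if f in ("pc1", "pc2"):
            cols += _CURVE_COLS
        elif f == "z_rs":
            cols.append("rs_pct")
        elif f in FEATURE_COLUMNS:
            cols.append(FEATURE_COLUMNS[f])
        elif f != "region":
            cols.append(f)
    return cols


def split_holdout(table: pd.DataFrame, fraction: float = 0.2, seed: int = 0):
    """Grouped train/holdout split by subject (default 80/20)."""
    gss = GroupShuffleSplit(n_splits=1, test_size=fraction, random_state=seed)
    tr, te = next(gss.split(table, groups=table["subject"]))
    return table.iloc[tr].reset_index(drop=True), table.iloc[te].reset_index(drop=True)


def holdout_evaluation(
    table: pd.DataFrame,
    feature_set,
    model_spec="rf",
    k: int = 5,
    holdout_fraction: float = 0.2,
    seed: int = 0,
) -> dict:
    """The 80/20 protocol: grouped holdout plus CV inside the 80 %.

    Subjects are split 80/20; k-fold grouped CV runs within the
    training 80 % (reported as ``cv``), then a single model fit on the
    whole 80 % is evaluated once on the held-out 20 % (``holdout``,
    with ROC curve points for plotting).
    """
    from sklearn.metrics import roc_curve

    train, hold = split_holdout(table, holdout_fraction, seed=seed)
    cv = crossval_classify(train, feature_set, model_spec, k=k, seed=seed)
    res = evaluate_external(train, hold, feature_set, model_spec, seed=seed)
    design = _FoldDesign(feature_set).fit(train)
    model = _make_model(model_spec, seed)
    model.fit(design.transform(train), train["severe"].to_numpy(bool))
    y = hold["severe"].to_numpy(bool)
    roc = None
    if len(np.unique(y)) == 2:
        fpr, tpr, _ = roc_curve(y, _predict_scores(model, design.transform(hold)))
        roc = np.column_stack([fpr, tpr]).tolist()
    return {"cv": cv.to_dict(), "holdout": res, "roc_points": roc}


def regional_prevalence(table: pd.DataFrame) -> pd.Series:
    """% of subjects with severe fibrosis, per region."""
    if table.empty:
        raise FeatureError("empty cohort")
    return table.groupby("region")["severe"].mean().mul(100.0).reindex(list(REGIONS))
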