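"""End-to-end orchestration: generate, analyze, report.

The pipeline persists every stage as plain files (VTK mesh series, CSV
tables, JSON reports) so that any stage can be re-run on user-supplied
data in the documented formats.  All randomness derives from the
config's global seed; rerunning a stage on unchanged inputs is
byte-identical, and a manifest with SHA-256 hashes, seeds and a config
echo accompanies every cohort.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .features import (
    CohortNormalization,
    SubjectRecord,
    build_feature_table,
    crossval_classify,
    feature_combination_sweep,
    evaluate_external,
    regional_prevalence,
)
from .fibres import map_fibres, rule_based_fibres
from .fibrosis import FibrosisConfig, compute_iir, regional_enhancement
from .mesh import load_mesh, save_mesh
from .parameterization import REGIONS, assign_regions, build_uac, triangle_regions
from .strain import MeshMotion, fibre_strain, regional_strain_curves, volume_curve
from .synthetic import CohortSpec

log = logging.getLogger("lastrain")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration (YAML-serializable)."""

    seed: int = 0
    cohorts: dict = field(default_factory=lambda: {
        "healthy": {"n_subjects": 10},
        "AF": {"n_subjects": 10},
    })
    antra_radius_mm: float = 10.0
    iir_threshold: float = 1.2
    projection_depth_mm: float = 3.0
    feature_sets: list = field(default_factory=lambda: [
        ["rs"], ["strain_rate"], ["pc1"], ["pc2"], ["region"],
        ["global_rs"], ["lav"], ["laef"], ["region", "lav", "laef"],
    ])
    classifier: dict = field(default_factory=lambda: {"kind": "rf", "n_estimators": 200})
    cv_folds: int = 5
    n_permutations: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise PipelineError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        if cfg.cv_folds < 2:
            raise PipelineError("cv_folds must be >= 2")
        for name, c in cfg.cohorts.items():
            if c.get("n_subjects", 1) < 1:
                raise PipelineError(f"cohort {name}: n_subjects must be >= 1")
        return cfg

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "cohorts": self.cohorts,
            "antra_radius_mm": self.antra_radius_mm,
            "iir_threshold": self.iir_threshold,
            "projection_depth_mm": self.projection_depth_mm,
            "feature_sets": self.feature_sets,
            "classifier": self.classifier,
            "cv_folds": self.cv_folds,
            "n_permutations": self.n_permutations,
            "log_level": self.log_level,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _cohort_spec(config: RunConfig, name: str) -> CohortSpec:
    opts = dict(config.cohorts[name])
    n = opts.pop("n_subjects")
    preset = opts.pop("preset", name if name in ("healthy", "AF", "DCM") else "AF")
    seed = opts.pop("seed", config.seed)
    opts.setdefault("antra_radius_mm", config.antra_radius_mm)
    return CohortSpec.preset(preset, n, seed=seed, **opts)


# ----------------------------------------------------------------------
# generate
# ----------------------------------------------------------------------

def run_generate(config: RunConfig, out_dir) -> Path:
    """Generate all configured cohorts and persist them with a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "cohorts": {}}
    for name in config.cohorts:
        spec = _cohort_spec(config, name)
        cdir = out / name
        cdir.mkdir(parents=True, exist_ok=True)
        log.info("generating cohort %s (n=%d, seed=%d)", name, spec.n_subjects, spec.seed)
        subjects, table = synthetic.generate_cohort(spec)
        files = []
        for s in subjects:
            sdir = cdir / s.subject_id
            sdir.mkdir(exist_ok=True)
            save_mesh(
                s.anatomy, sdir / "reference.vtk",
                extra_point_data={"intensity": s.vertex_intensity},
            )
            from .mesh import write_vtk

            for ti in range(s.motion.n_frames):
                write_vtk(
                    sdir / f"frame_{ti:03d}.vtk", s.motion.frames[ti],
                    s.anatomy.triangles, comment=f"{s.subject_id} frame {ti}",
                )
            (sdir / "subject.json").write_text(json.dumps({
                "subject_id": s.subject_id,
                "blood_pool_mean": s.blood_pool_mean,
                "frame_times": s.motion.frame_times.tolist(),
                "center": s.center.tolist(),
            }, indent=1))
            files += sorted(str(p.relative_to(out)) for p in sdir.iterdir())
        table.to_csv(cdir / "truth.csv", index=False)
        files.append(str((cdir / "truth.csv").relative_to(out)))
        manifest["cohorts"][name] = {
            "spec": spec.to_dict(),
            "n_subjects": spec.n_subjects,
            "truth_rows": int(len(table)),
            "files": {f: _sha256(out / f) for f in files},
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    return out


def load_cohort_subject(cohort_dir: Path, subject_id: str):
    """Load one persisted subject back into memory."""
    sdir = Path(cohort_dir) / subject_id
    if not sdir.exists():
        raise PipelineError(f"missing subject directory {sdir} (stage: generate)")
    mesh = load_mesh(sdir / "reference.vtk")
    from .mesh import read_vtk

    _, _, pdata, _ = read_vtk(sdir / "reference.vtk")
    meta = json.loads((sdir / "subject.json").read_text())
    frame_files = sorted(sdir.glob("frame_*.vtk"))
    frames = np.stack([read_vtk(f)[0] for f in frame_files])
    motion = MeshMotion(mesh, frames, np.asarray(meta["frame_times"]))
    return mesh, motion, pdata["intensity"], meta


# ----------------------------------------------------------------------
# analyze
# ----------------------------------------------------------------------

def analyze_subject(
    mesh, motion, intensity, blood_pool_mean,
    antra_radius_mm=10.0, fibrosis_config=None, with_fibres=True,
    subject_id="subject",
):
    """Run the measurement pipeline on one subject.

    Parcellation -> fibrosis quantification -> strain curves -> volume
    curve; returns a :class:`SubjectRecord` plus the intermediate maps.
    """
    cfg = fibrosis_config or FibrosisConfig()
    uac = build_uac(mesh)
    regions = assign_regions(mesh, uac, antra_radius_mm)
    tri_regs = triangle_regions(mesh, regions)

    iir = compute_iir(intensity, blood_pool_mean)
    fmap = regional_enhancement(mesh, iir, tri_regs, cfg)

    curves = regional_strain_curves(motion, tri_regs)
    vols, gf = volume_curve(motion)

    fibre_rs = None
    if with_fibres:
        fibres = rule_based_fibres(mesh)
        fs = fibre_strain(motion, fibres.endo)
        fibre_rs = {}
        for r in REGIONS:
            mask = tri_regs == r
            curve = fs[:, mask].mean(axis=1)
            fibre_rs[r] = float(curve.max() - curve.min())

    record = SubjectRecord(
        subject_id=subject_id,
        regional_curves={r: curves.regional[r] for r in REGIONS},
        frame_times=motion.frame_times,
        global_curve=curves.global_curve,
        lav_max_ml=gf.lav_max_ml,
        laef_pct=gf.laef_pct,
        severe=dict(fmap.severe),
        enhancement_pct=dict(fmap.enhancement_pct),
        fibre_rs=fibre_rs,
    )
    return record, fmap, curves, gf


def run_analyze(config: RunConfig, cohort_dir, out_dir) -> Path:
    """Analyze a generated cohort directory end to end.

    Stage outputs (feature tables, fibrosis maps, classification
    reports) are persisted as CSV/JSON; existing stage outputs are
    reused (stage-level resume).
    """
    cohort_dir = Path(cohort_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = cohort_dir / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError(f"missing {manifest_path} (stage: generate)")
    manifest = json.loads(manifest_path.read_text())

    tables = {}
    for name in manifest["cohorts"]:
        table_path = out / f"features_{name}.csv"
        fib_path = out / f"fibrosis_{name}.csv"
        if table_path.exists() and fib_path.exists():
            log.info("cohort %s: reusing existing feature table", name)
            tables[name] = pd.read_csv(table_path)
            continue
        records, fib_rows = [], []
        subject_ids = sorted({
            Path(f).parts[1] for f in manifest["cohorts"][name]["files"]
            if len(Path(f).parts) > 2
        })
        for sid in subject_ids:
            try:
                mesh, motion, intensity, meta = load_cohort_subject(cohort_dir / name, sid)
            except Exception as exc:
                raise PipelineError(
                    f"cohort {name}, subject {sid}: failed to load mesh/motion "
                    f"(stage: analyze/load): {exc}"
                ) from exc
            rec, fmap, _, _ = analyze_subject(
                mesh, motion, intensity, meta["blood_pool_mean"],
                antra_radius_mm=config.antra_radius_mm,
                fibrosis_config=FibrosisConfig(
                    iir_threshold=config.iir_threshold,
                    projection_depth_mm=config.projection_depth_mm,
                ),
                subject_id=sid,
            )
            records.append(rec)
            fib_rows.append(fmap.to_frame(subject=sid))
        table = build_feature_table(records)
        table.to_csv(table_path, index=False)
        pd.concat(fib_rows).to_csv(fib_path, index=False)
        tables[name] = table

    # classification on the AF-like cohort, normalized by the healthy one
    report = {
        "config": config.to_dict(),
        "feature_sets": {},
        "prevalence": {},
        "external": {},
        "holdout": {},
    }
    primary = "AF" if "AF" in tables else list(tables)[0]
    table = tables[primary]
    if "healthy" in tables:
        norm = CohortNormalization.from_table(tables["healthy"])
        table = table.copy()
        table["z_rs"] = [
            float((x - norm.mu[r]) / norm.sd[r])
            for x, r in zip(table["rs_pct"], table["region"])
        ]
    from .features import FeatureError

    for fs in config.feature_sets:
        try:
            rep = crossval_classify(
                table, tuple(fs), config.classifier, k=config.cv_folds, seed=config.seed
            )
            report["feature_sets"]["+".join(fs)] = rep.to_dict()
        except FeatureError as exc:
            report["feature_sets"]["+".join(fs)] = {"error": str(exc)}
    report["prevalence"][primary] = regional_prevalence(table).to_dict()
    try:
        from .features import holdout_evaluation

        hold = holdout_evaluation(
            table, ("region", "lav", "laef"), config.classifier,
            k=config.cv_folds, seed=config.seed,
        )
        report["holdout"] = {k: v for k, v in hold.items() if k != "roc_points"}
        if hold["roc_points"]:
            roc = pd.DataFrame(hold["roc_points"], columns=["fpr", "tpr"])
            roc.to_csv(out / "roc_region_lav_laef.csv", index=False)
    except FeatureError as exc:
        report["holdout"] = {"error": str(exc)}
    for name, other in tables.items():
        if name == primary:
            continue
        try:
            report["external"][name] = evaluate_external(
                table, other, ("region", "lav", "laef"), config.classifier,
                seed=config.seed,
            )
        except FeatureError as exc:
            report["external"][name] = {"error": str(exc)}
    (out / "classification.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return out


# ----------------------------------------------------------------------
# report
# ----------------------------------------------------------------------

def run_report(results_dir) -> str:
    """Render a plain-text summary of the classification results."""
    results_dir = Path(results_dir)
    path = results_dir / "classification.json"
    if not path.exists():
        raise PipelineError(f"no classification.json under {results_dir}")
    rep = json.loads(path.read_text())
    if not rep.get("feature_sets"):
        raise PipelineError("classification report contains no feature sets")

    lines = ["Severe-fibrosis classification (grouped 5-fold CV)", ""]
    lines.append(f"{'feature set':<24} {'accuracy %':>14} {'ROC AUC':>14}")
    for name, d in rep["feature_sets"].items():
        if "error" in d:
            lines.append(f"{name:<24} failed: {d['error']}")
            continue
        for key in ("mean_accuracy_pct", "mean_auc"):
            if key not in d:
                raise PipelineError(f"feature set {name}: missing {key}")
        lines.append(
            f"{name:<24} {d['mean_accuracy_pct']:>7.1f} ± {d['sd_accuracy_pct']:<4.1f}"
            f" {d['mean_auc']:>7.3f} ± {d['sd_auc']:<5.3f}"
        )
    for cohort, prev in rep.get("prevalence", {}).items():
        lines += ["", f"Regional severe-fibrosis prevalence ({cohort}):"]
        for region, pct in prev.items():
            bar = "#" * int(round(pct / 4)) if pct == pct else ""
            lines.append(f"  {region:<10} {pct:>5.1f}%  {bar}")
    for cohort, ext in rep.get("external", {}).items():
        lines.append("")
        if "error" in ext:
            lines.append(f"External evaluation on {cohort} failed: {ext['error']}")
            continue
        auc = "n/a" if ext.get("auc") is None else f"{ext['auc']:.3f}"
        lines.append(
            f"External evaluation on {cohort}: accuracy "
            f"{ext['accuracy_pct']:.1f}%, AUC {auc} (n={ext['n_test']})"
        )
    return "\n".join(lines)
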