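# lastrain

Regional 3D strain and fibrosis analysis of the left atrium (LA) on
triangulated surface meshes.

Atrial fibrillation is sustained by structural remodeling of the LA —
dilation, loss of emptying function, and wall fibrosis that appears
bright on late-gadolinium-enhancement (LGE) CMR. A natural question
for anyone planning ablation or studying remodeling is whether
*regional* wall function (strain) marks *regional* fibrosis, or
whether fibrosis tracks only global remodeling. `lastrain` implements
the full analysis chain needed to ask that question quantitatively,
plus a seeded synthetic cohort generator so that every stage is
testable against known ground truth:

* **Geometry** — labeled LA surfaces (body, four pulmonary veins,
  appendage, mitral rim); two discrete-harmonic surface coordinates
  (cotangent Laplacian, Dirichlet anchors) in the role of universal
  atrial coordinates; the six-region parcellation (left/right PV
  antra by 10 mm geodesic distance from the vein junctions, plus
  posterior, septal, anterior, lateral walls); atlas fibre-field
  transfer through the coordinate chart; capped divergence-theorem
  volumes with the LAA and PVs excluded.
* **Fibrosis** — image intensity ratio IIR = I / mean(blood pool),
  enhancement = % of regional surface area with IIR > 1.2, staging
  1–4 at 10/20/30 % with stage 4 (> 30 %) = severe; normal-ray image
  sampling and blood-pool estimation from NIfTI volumes.
* **Strain** — area strain per element, ε(t) = 100·(A(t) − A(0))/A(0)
  initialized at LVED; regional ratio-of-sums curves; engineering
  fibre strain; LAV(t) and LAEF = 100·(V_max − V_min)/V_max; a
  simplified ray-casting surface tracker for uncorresponded frames.
* **Features & classification** — reservoir strain (curve amplitude),
  peak strain rate, strain-curve principal components, healthy-cohort
  z-scores z = (x − μ_H)/σ_H; grouped stratified 5-fold
  cross-validation of severe-fibrosis classifiers (random forest by
  default) with block-permutation p-values and external-cohort
  evaluation.
* **Synthetic cohorts** — healthy / AF / DCM-like presets with
  realistic regional strain distributions, regional fibrosis patterns,
  and severe fibrosis linked to LAV, LAEF and region while strain is
  decoupled — a known answer against which the classifier harness is
  validated.

## A worked example

Running `python examples/04_classification.py` (a 30-subject AF-like
cohort) prints:

```
regional severe-fibrosis prevalence (% of subjects):
region
LPVA         46.7
RPVA         46.7
posterior    66.7
septal       60.0
anterior     63.3
lateral      73.3

feature set          accuracy %   ROC AUC
rs                   47.8 ± 11.4  0.445
pc1                  48.3 ± 7.5   0.446
region               59.4 ± 3.2   0.602
lav                  63.9 ± 7.1   0.596
laef                 65.0 ± 8.0   0.668
region+lav+laef      78.9 ± 9.9   0.861

regional RS permutation p-values: accuracy 0.98, AUC 0.96
```

Severe fibrosis is most prevalent in the lateral and posterior walls;
regional reservoir strain alone classifies severe fibrosis at chance
(AUC ≈ 0.45, permutation p ≈ 1), while region + LAV + LAEF classifies
it well (accuracy ≈ 79 %, AUC ≈ 0.86) — the structural signature the
pipeline is designed to detect. `examples/` contains three more
narrative scripts (anatomy and parcellation, fibrosis quantification
through an image round trip, strain/volume/tracking).

There is also a thin CLI for running the staged pipeline on disk:
`lastrain generate|analyze|report` with a YAML config (see
`lastrain.pipeline.RunConfig`).

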