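# Methods

`lastrain` relates regional left-atrial (LA) function to regional
fibrosis on triangulated endocardial surface meshes. This note records
the models and conventions the package implements, the choices made
where more than one convention is defensible, and what the synthetic
cohorts do and do not emulate.

## Surface model and parameterization

The LA is a labeled triangulated surface in millimetres: an orientable
2-manifold whose only boundaries are the mitral annulus and the
openings of the four pulmonary veins (PVs) and the appendage (LAA).
Every vertex carries one anatomical label (`body`, the four PV labels,
`LAA`, `mitral_rim`), and named landmark sets store the PV–LA junction
rings and the anchor sets of the surface coordinates.

Two discrete-harmonic coordinates are solved on the body with a
cotangent-weight graph Laplacian and Dirichlet data on anchor sets:
`alpha` runs lateral (0) → septal (1) and `beta` posterior (0) →
anterior (1). Edges whose summed cotangent weight is negative (obtuse
triangle pairs) fall back to unit weight so the system stays an
M-matrix and the discrete maximum principle holds; numerically-zero
weights are kept at zero so linear fields on planar meshes are
reproduced exactly. This construction keeps the two roles the
coordinates play downstream — consistent regional mapping and
atlas-field transfer — without reproducing any particular published
atlas algorithm.

**Parcellation.** The PV antra are the body vertices within 10 mm
(strict inequality; the junction ring itself is antral) geodesic
distance of the left / right junction rings; geodesic distance is
shortest-path over the edge graph with Euclidean edge lengths, which
is exactly Dijkstra-testable and second-order close to the true
surface geodesic at antral scale. The remaining body is split in the
(alpha, beta) chart: beta below 1/3 is posterior, above 2/3 anterior;
the roof band splits lateral (alpha < 1/3) / septal (alpha > 2/3),
with the middle of the roof divided posterior/anterior at beta = 0.5.
These thresholds are configuration values (`RegionThresholds`), not
measurements: no printed thresholds exist for this parcellation, so
the defaults were chosen once to give six contiguous, plausibly
proportioned regions and are deliberately easy to override.

**Fibre transfer.** Per-triangle unit tangent fibre vectors
(endocardial/epicardial) are carried between meshes through the chart:
each target triangle takes the fibre of the atlas triangle nearest in
(alpha, beta), expressed in an orthonormal tangent frame built from
the stronger chart gradient and its in-plane normal rotation, and
rebuilt in the target triangle's frame. Frame transport (rather than
copy-and-project) makes the transfer exact under rigid motion.

## Volumes

Enclosed volume is the divergence-theorem volume of the capped body:
triangles touching an excluded label (LAA + PVs by convention) are
dropped, every boundary loop (including the mitral rim) is closed with
a fan lid at its centroid, and the signed volume of the resulting
closed polyhedron is summed exactly. Dropping triangles can pinch the
boundary at single vertices; the excluded set is grown at pinch points
until the boundary is a union of simple loops. LAV is reported in mL;
LAEF = 100·(LAV_max − LAV_min)/LAV_max.

## Strain

All strain is initialized at the LVED frame (frame 0 of the motion;
the atrial minimum-volume phase). Element area strain at frame *t* is
100·(A(t) − A(0))/A(0). Regional curves use the ratio-of-sums: the
strain of the summed regional area, which is robust to small-element
noise (a mean-of-elements variant is selectable). Fibre strain treats
the fibre as a material direction convected by the triangle's edge
vectors and reports engineering stretch, 100·(λ − 1), not
Green–Lagrange. Curves from differing frame counts are aligned by
periodic linear resampling onto a uniform 30-point cycle grid,
preserving the phase-0 value.

**Surface tracker.** When per-frame surfaces are not
vertex-corresponded, a simplified tracker recovers correspondence:
rays are cast from the reference chamber centroid through each current
vertex onto the target surface (the natural correspondence for a
star-shaped chamber under inflation/deflation; vertex-normal and
closest-point modes are available), open-boundary vertices track the
target's boundary rings, the displacement field is regularized by
solving (I + wL)d = d_raw with the uniform graph Laplacian
(w = 0.25 by default), and a final hard projection pins the estimate
onto the target so the tracked mesh keeps full surface coverage.
Plain closest-point correspondence was evaluated and rejected: it
loses coverage at the rims and drifts systematically at the
high-curvature poles, with regional reservoir-strain errors of 20–50 %
on synthetic motion; ray casting brings the worst-case error on the
moderate-amplitude fixture below 8 %. The tracker is a stand-in for
registration-based feature tracking; its acceptance surface is strain
recovery on synthetic truth, not registration fidelity, and its
fidelity on real image-derived surfaces is untested.

## Fibrosis quantification

Enhancement is defined by the image intensity ratio (IIR): per-vertex
LGE intensity divided by the mean blood-pool intensity, thresholded at
1.2. A triangle is enhanced if the mean of its three vertex IIRs
exceeds the threshold (a per-vertex area-share rule is selectable);
regional enhancement is the enhanced fraction of regional surface
area, in %. Stages: [0, 10) → 1, [10, 20) → 2, [20, 30] → 3, and
stage 4 ("severe") strictly above 30 % — the half-open boundary
convention is a declared choice; exactly 30.0 % is stage 3. Image
sampling onto the surface takes the maximum trilinearly interpolated
intensity along the outward vertex normal over ±3 mm (bright-rim
capture); the blood-pool mean is estimated from voxels inside the
capped body farther than the projection depth from the wall.

## The synthetic cohorts

The generator exists so that every stage of the analysis is testable
against known truth without any imaging data. Its defaults encode the
structure the analysis is designed to detect:

* **Anatomy** — an icosphere deformed to a subject-specific ellipsoid
  (~5 % axis variability) with radially extruded PV and LAA stubs
  opened at their tips and an open mitral annulus; star-shaped about
  its centre by construction, which makes voxelization and containment
  exact. Size is rescaled so the capped body volume equals the
  subject's LVED volume exactly.
* **Wall corrugation** — a ±10 % high-frequency radial texture
  (alternate-sign graph coloring) baked into the reference wall. This
  is the geometric degree of freedom that decouples wall area from
  enclosed volume: a purely radial motion cannot set regional strain
  and LAEF independently (scaling multiplies areas by s² and volume by
  s³, and the isoperimetric inequality pins their ratio), whereas
  corrugation that deepens or flattens over the cycle changes area at
  nearly constant volume — loosely, trabeculated wall texture
  smoothing out as the chamber distends.
* **Motion** — one cycle of `frames_per_cycle` (default 30) frames.
  The volume curve follows a smooth biphasic envelope (reservoir
  filling peak near 40 % of the cycle, late-diastolic shoulder before
  booster ejection) between the subject's V_min and V_max; every
  regional area curve is pinned to the *same* normalized envelope with
  region-specific amplitude, by solving per frame for the corrugation
  level (common-mode area), region-wise smooth stretches (regional
  pattern) and a global homothety (exact volume). Pinning the curve
  shape is deliberate: shape then carries no subject-level
  information, so strain-curve principal components cannot act as a
  hidden proxy for LAEF. Regional reservoir-strain targets are
  gamma-distributed (non-negative, first two moments matched to the
  cohort: healthy 48.0 ± 33.2 %, AF 19.5 ± 15.7 %) with mild fixed
  regional weighting (septum strongest, PV antra weakest), drawn
  independently of LAV and LAEF.
* **Fibrosis** — severe status per region is Bernoulli with log-odds
  `intercept + 2.0·z(LAV) − 2.0·z(LAEF) + region offset` (an optional
  strain-coupling term is off by default); region offsets and
  intercepts were calibrated once against the published AF pattern
  (lateral ≈ 85 % and posterior ≈ 66 % of subjects severe, ≈ 62 % of
  all regions severe; regional burden means lateral 44.4, posterior
  40.9, septal 32.7, anterior 31.4, LPVA 26.0 %, with the unreported
  RPVA set between LPVA and anterior). The enhancement target is drawn
  on the matching side of the 30 % cut and realized by growing 1–2
  contiguous painted patches vertex-by-vertex until the measured
  above-threshold area fraction matches the target within ~1 %;
  enhanced vertices sit at IIR 1.5, background at 0.9, Gaussian noise
  is added after the noise-free truth is measured.
* **Truth closure** — every stored truth value (regional curves,
  volumes, enhancement, stages) is *measured* from the generated
  surfaces and intensities with the same package operations the
  analysis uses, so pipeline-vs-truth agreement is exact by
  construction on noise-free subjects.

What the cohorts do **not** emulate: MR physics (bias fields, partial
volume, banding), wall thickness and transmurality, dense-vs-patchy
fibrosis texture, fibre-mediated mechanics, beat-to-beat variability,
and real registration error — the tracker is tested against clean
synthetic surfaces only. Passing tests therefore demonstrate the
correctness and statistical behaviour of the *analysis*, not the
performance of any image-processing front end on clinical data.

## Classification harness

One row per (subject, region): regional area reservoir strain (curve
amplitude, max − min), peak area strain rate (max |dε/dt| over the
cycle, central differences with one-sided ends), the first two
principal-component scores of the 30-point resampled curves, optional
fibre reservoir strain, and the subject's global reservoir strain,
LAV and LAEF; the label is the severe flag. Z-scores against a healthy
reference follow z = (x − μ_healthy)/σ_healthy per region.

Cross-validation is stratified by label and grouped by subject (all
six regions share a fold) to prevent leakage through the subject-level
global features; metrics are mean ± SD fold accuracy and ROC AUC. The
model is pluggable (random forest default, 200 trees; logistic
regression and gradient boosting selectable). Everything fit from data
— PCA loadings, z-normalizations, the model — is fit on training folds
only. Significance is by permutation: whole-subject label blocks are
reassigned across subjects (region-aligned, preserving within-subject
label correlation), and p = (1 + #{permuted ≥ observed})/(n_perm + 1),
which is strictly positive and conservative. The published 80/20 split
plus 5-fold CV is realized as a grouped 20 % holdout with 5-fold CV
inside the 80 %.

## Problem sizes and numerical choices

Default meshes are icosphere subdivision 3 (~570 vertices, ~1090
triangles after openings), which makes a full 47-subject cohort with
30-frame motion and painted fibrosis generate in well under a minute
and keeps the painting granularity (~0.5 % of a region per triangle)
inside the 1 % closure tolerance. Harmonic solves use sparse direct
factorization; the motion solver runs at most five fixed-point
iterations (typical residual < 0.1 strain points); permutation tests
in the test-suite use the logistic model with 99 permutations and
3 folds, which preserves the validity (though not the power) of the
permutation p-value. Degenerate inputs raise typed errors
(`MeshError`, `ParameterizationError`, `StrainError`, `FibrosisError`,
`GeneratorError`, `FeatureError`) naming the offending entity.

## Known limitations

* The (alpha, beta) region thresholds and the antral-distance metric
  are declared defaults, not inferred from any dataset.
* The tracker is validated on moderate-amplitude synthetic motion
  only; very small regional strains (< ~10 %) have relative errors
  above 10 % simply because the absolute error floor (~1–2 strain
  points) dominates.
* The DCM-like preset is a generic intermediate-remodeling cohort; it
  is *not* calibrated to familial-DCM physiology beyond size/function
  shifts, so external-cohort numbers on it characterize the harness,
  not the disease.
* Staging behaviour exactly at the 10/20/30 % cuts follows the
  declared half-open convention; data landing exactly on a cut are
  measure-zero in practice but the convention matters for tests.
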