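# Methods

`glomorph` quantifies renal ultrastructure from calibrated TEM instance
segmentation masks and classifies seven glomerulopathy subtypes from the
resulting measurements. The engine is purely mask-driven: it never sees
image intensities, only labeled pixel sets (or polygons) for three classes —
glomerular basement membrane (GBM), podocyte foot processes (FP), and
electron-dense deposits (EDD) — together with a physical calibration in
nm/pixel. No default calibration is assumed; the pixel size must always be
supplied.

## GBM morphometry

Candidate GBM instances pass through a fixed chain:

1. **Small-area exclusion** (default `min_area_px2 = 500`) and
   **morphological opening** with a disk of radius 1 px to remove speckle
   artifacts. If opening splits an instance the largest component is kept;
   if it annihilates one, the instance is flagged rather than raising.
2. **Shape description.** The perimeter is the polygonal length of the
   traced iso-0.5 contour, the area the pixel count; compactness is
   `C = 4πA/P²` and fill rate `F = A / A_hull` with the hull taken as the
   convex-hull pixel count (so `F ≤ 1` holds under discretization). The
   contour used downstream is smoothed by Douglas–Peucker approximation
   with tolerance `0.002 · P`.
3. **Skeletonization.** The instance (with speckle holes filled — holes are
   filled unless they are both large, >2 % of the instance area, and fat,
   inscribed radius ≥ 3 px; this preserves genuine annular lumina while
   removing rasterization cracks) is thinned to a single-pixel centerline.
   The main centerline is the diameter path of the skeleton's 8-connected
   graph (double Dijkstra sweep), which bypasses side branches instead of
   depending on their removal; spur branches shorter than
   `max(10 px, 1.5 × max EDT)` are then pruned — with the centerline
   protected — for the branch statistics. The path is truncated where the
   local half-width (Euclidean distance transform, EDT) drops below 0.9×
   its median along the path — thinning veers toward the acute corner of a
   cut end, and this keeps the path on the constant-width core.
4. **Skeleton length and thickness.** Raw pixel-step sums overestimate the
   length of oblique digitized curves by up to ~8 %, so length is measured
   on a moving-average-smoothed copy of the path. Because thinning retreats
   about half the local width from each free end, the EDT value at each
   endpoint is added back. With those two corrections the skeleton-method
   thickness is literally `area / length`, and it is unbiased to within
   ~2 % on constant-width phantoms across 150–800 nm and 1–4 nm/px.
5. **Boundary-method thickness.** The smoothed contour is divided into
   inner and outer sides: for an annulus the hole contour is the inner
   side; for an open ribbon the contour is split at the two vertices
   nearest the skeleton endpoints, and the shorter arc is called inner (the
   designation is arbitrary; the mask cannot encode biological sidedness).
   End caps are excluded by trimming 1.5 local widths from the inner arc
   and 0.5 from the outer arc at each split. Each inner sample contributes
   its Euclidean distance to the nearest outer sample; the mean is the
   thickness. Instances without a two-sided partition (blobs) are flagged
   `no_ribbon_partition` and rejected.
6. **Skeleton quality.** Curvature is estimated by finite differences of
   the tangent angle along the coordinate-smoothed path (window w = 5 px;
   the lattice path is low-pass filtered first, otherwise pixel
   quantization dominates |κ|). The normalized scores are
   `κ̂ = w · mean|κ|` and `B̂ = B / L` with B the count of skeleton pixels
   having more than two neighbors; their standard deviations (σ_κ over
   curvature samples, σ_B of the per-pixel branch indicator) measure
   smoothness and complexity.
7. **Filtering.** An instance is accepted iff `C ∈ (0, 0.35]`, `F ≥ 0.05`,
   `κ̂ ≤ 0.5` and `B̂ ≤ 0.05`. These numeric defaults were calibrated on
   phantoms — elongated membranes sit well below `C = 0.35` once their
   length exceeds ~8 widths, while blob-like false detections score
   `C ≈ 0.8–0.9` — and are all configurable. Rejected instances are kept
   with reason codes.

The per-image summary pools accepted instances; the skeleton method
(length-weighted mean of per-instance area/length) is the default headline
thickness, with the boundary method available by configuration — both are
always computed and reported per instance.

## Foot-process effacement and deposits

FP density is `ρ = N / L` with N the number of FP instances whose centroid
lies within 20 px of accepted GBM pixels and L the accepted skeleton length
in µm. The effacement fraction is the linear bridge
`f = clamp(1 − ρ/ρ_ref, 0, 1)` against a reference (normal) density
`ρ_ref = 5 FP/µm` — the package's choice, corresponding to a ~200 nm
foot-process pitch on a healthy membrane, and shared by the phantom
generator so that generated and measured fractions are commensurable.
Grading follows the 4-level clinical standard with left-closed intervals:
f < 0.10 no fusion, 0.10–0.50 segmental, 0.50–0.80 extensive, ≥ 0.80
diffuse; the diffuse dichotomy drives patient-level classification. For
deposits only presence/absence is judged (site localization is out of
scope): instances below 500 nm² are discarded as speckle and presence is
`count > 0`.

## Subtype classification

Per-image features form two named blocks: a statistical block (thickness
mean/SD/min/max, compactness/fill-rate/curvature statistics, GBM count and
total length, FP count/density/effacement/grade one-hot/diffuse flag, EDD
presence/count/area, plus missing-block flags) and an optional 32-dim
embedding block from a pluggable hook. The default hook is a classical
descriptor — a 16-bin histogram of contour tangent orientations plus 16
normalized quantiles of the pooled thickness profile — keeping the
two-block fusion architecture without any trained image encoder.

Feature selection is L1-penalized multinomial logistic regression over a
log-spaced penalty grid, scored by stratified cross-validated
misclassification and resolved by the one-standard-error rule (the
sparsest penalty within 1 SE of the best); features with any nonzero
coefficient are retained. If the support empties, all features are
retained with a warning. NaNs are imputed with training-set medians;
standardization is learned on training data only.

The classifier is a stacking ensemble: four base learners of distinct
families (RBF SVM, XGBoost, k-nearest neighbors, LightGBM) produce
stratified 5-fold out-of-fold class probabilities; the meta-model is
one-vs-rest least squares on the stacked 28-dim probabilities (+intercept),
with scores clipped at zero and renormalized to the probability simplex —
the closest linear-regression meta-model that still yields probabilities.
Base learners are refitted on all data after the meta fit. All randomness
flows from a single integer seed stored in the model artifact (JSON
manifest + joblib sidecar).

## Phantom generator

Real TEM cohorts are not redistributable, so every claim is exercised on
synthetic phantoms with exact ground truth:

* **GBM ribbons**: pixels within half the true width of a sinusoidal
  centerline (amplitude/period configurable); boundary noise perturbs the
  local half-width with a smoothed Gaussian field. Truth records the exact
  width and centerline length; generated area/(length·width) stays within
  [0.9, 1.1].
* **FP bands**: disks along the upper ribbon side at the reference spacing
  `1/ρ_ref`; a contiguous stretch covering the effaced fraction of the
  centerline carries none. Effacement is thus modeled as FP *absence*,
  matching the density route by which it is detected.
* **EDD blobs**: ellipses of configurable area adjacent to the lower side.
* **Artifacts**: compact disks labeled GBM, emulating false detections.

Subtype-conditioned presets (`presets/subtypes.yaml`) encode textbook
tendencies at 8 nm/px on 224×768 images: thin membranes in TBMN (~200 nm),
thickened in MN (~640) and DN (~780), diffuse effacement in MCD and MN,
deposits in IgA/LN/MsPGN/MN with class-typical counts and areas. The
numbers are explicitly synthetic calibration values, not measurements from
any cohort. Cohort allocation is deterministic largest-remainder (balanced
n = 700 → exactly 100 per class); per-sample draws come from seed-sequence
children, so datasets are byte-reproducible from one seed.

What passing phantom tests does **not** show: robustness to real
segmentation-model error modes (ragged masks, merged instances, missed
membranes), to intensity-dependent artifacts, or to anatomies outside the
generator's vocabulary (capillary loops cut obliquely, double contours,
subepithelial spikes). The phantoms validate the measurement arithmetic
and the architecture, not clinical performance.

## Problem sizes and numerics

The shipped benchmarks use: a 50-ribbon thickness sweep (widths 150–800 nm
× 1–4 nm/px); 5 filtering phantoms (10 ribbons + 5 artifacts); and an
n = 700 balanced 7-class cohort with an 80/20 stratified holdout — sizes
chosen so the whole suite and the reproduction script each run on a single
CPU in minutes. Tolerances asserted by the tests: ≤5 % bias and MAE for
both thickness estimators, ≤0.15 relative estimator disagreement, ≤0.1
absolute error on effacement recovery, ≥0.90 end-to-end holdout accuracy.
Degenerate inputs are contracts, not crashes: empty mask sets, sub-min-area
blobs, single-pixel instances, 1-px lines (their skeleton is the instance
itself), annuli, and instances annihilated by opening are all handled and
covered by tests.

Confidence intervals, where requested, use the nonparametric percentile
bootstrap (B = 2000, seeded). AUC is the Mann–Whitney rank statistic with
ties averaged; macro AUC averages per-class one-vs-rest AUCs (zero-support
classes excluded with a warning) and micro AUC pools all (sample, class)
decisions. Dice of two empty masks is defined as 1 (logged). Decision
curves use `NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t)` per class one-vs-rest
with treat-all/treat-none references.

## Known limitations

* Inner/outer side assignment is geometric, not biological; the boundary
  method reports an unsigned nearest-distance width.
* The skeleton method assumes ribbon topology; heavily branched or netted
  masks are rejected rather than measured.
* The effacement bridge is linear in density; real grading integrates
  morphology beyond counts.
* Per-image (not per-patient) classification is the default; a
  mean-probability pooling over a patient's images is available in the
  library but unexercised by the benchmarks.
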