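# glomorph

Quantitative morphometry of renal ultrastructure from transmission electron
microscopy (TEM) segmentation masks, with 7-class glomerulopathy subtype
classification.

Diagnosing glomerular disease on TEM rests on three ultrastructural
readouts: the thickness of the glomerular basement membrane (GBM — thin in
thin-basement-membrane nephropathy, thickened in membranous and diabetic
nephropathy), the degree of podocyte foot-process (FP) fusion
("effacement", the hallmark of minimal change disease), and the presence of
electron-dense deposits (EDD, marking immune-mediated disease). `glomorph`
takes calibrated instance segmentation masks of these three structures —
integer label images or COCO-style polygon JSON, plus a nm/pixel scale —
and turns them into reproducible measurements and a subtype call. It is
the measurement and classification back end for any detector/segmenter
that can emit masks; no image intensities are used.

## What it computes

**GBM thickness**, by two estimators on each cleaned, filtered ribbon:

* *skeleton method*: `t̄ = A / L`, the instance area divided by the length
  of its single-pixel centerline (spur-pruned and end-corrected);
* *boundary method*: the mean Euclidean distance from each sample on the
  inner contour side to the nearest sample on the outer side.

False-positive detections are rejected by shape and skeleton-quality
criteria: compactness `C = 4πA/P²`, fill rate `F = A/A_hull`, normalized
curvature `κ̂ = w·mean|κ|` and branch score `B̂ = B/L`.

**FP effacement**: density `ρ = N/L` (FPs per µm of membrane), effacement
fraction `f = clamp(1 − ρ/ρ_ref, 0, 1)`, and the 4-level clinical grade —
no fusion (f < 10 %), segmental (10–50 %), extensive (50–80 %), diffuse
(≥ 80 %) — plus the diffuse-fusion dichotomy.

**EDD presence** after a minimum-area speckle filter.

**Subtype classification** (MCD, MN, IgA, LN, DN, MsPGN, TBMN): measurement
statistics plus an optional 32-dim embedding block are concatenated,
LASSO-selected (multinomial L1 with the one-standard-error rule), and fed
to a stacking ensemble — four base learners (RBF SVM, XGBoost, k-NN,
LightGBM) whose out-of-fold class probabilities are combined by a linear
meta-model renormalized to the probability simplex.

A seeded phantom generator (ribbons of controlled true width, FP bands
with a controlled effaced fraction, elliptical deposits,
subtype-conditioned cohorts) provides exact ground truth for every stage;
see `docs/methods.md` for the model, parameter defaults, and what the
phantoms do and do not establish.

## Worked example

```python
from glomorph import PhantomSpec, generate_phantom, measure_mask_set

spec = PhantomSpec(
    nm_per_pixel=8.0, image_height=224, image_width=768,
    width_nm=350.0, waviness_amplitude_px=12, waviness_period_px=300,
    boundary_noise_sd_px=0.5, fp_enabled=True, effaced_fraction=0.55,
    edd_present=True, edd_count=4,
)
mask_set, truth = generate_phantom(spec, 42)
record = measure_mask_set(mask_set)
```

prints, when the fields are formatted:

```
GBM instances accepted : 1
mean thickness         : 347.6 nm  (true 350.0)
FP density             : 2.23 /um
effacement fraction    : 0.55  (true 0.55)
fusion grade           : extensive
EDD present            : True  (n=4)
```

The 350 nm ribbon is recovered to within 1 %; the generated 55 % effaced
stretch comes back as f = 0.55, which the threshold table grades
*extensive* (50–80 %); the four deposits survive the area filter. The same
flow works on real masks via `glomorph measure --mask labels.png
--nm-per-px 2.3 --out out/` (the calibration is always explicit — there is
no defensible default pixel size).

The CLI also exposes `simulate` (phantom cohorts as label PNGs + truth
CSV), `train` / `classify` (the stacking model), and `evaluate`
(classification reports with per-class and macro/micro AUC, confusion
matrices, decision-curve net benefit).

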