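# Methods

## The problem

The mitotic-cell count is the strongest proliferation biomarker in breast-cancer
grading: a pathologist counts dividing nuclei over ten high-power fields (HPFs,
2084 × 2084-pixel H&E tiles at 40×) and maps the total onto the Nottingham
mitotic score. Automating the count is hard because mitotic figures — dark,
bluish, irregularly textured nuclei — closely resemble ordinary hyperchromatic
nuclei and apoptotic bodies, so any sensitive detector produces many false
positives that must be filtered.

`mitodetect` implements a multi-stage detection architecture around that
problem: (1) a scored candidate detector, (2) a per-feature threshold cascade
over handcrafted features, (3) hierarchical score-level fusion of two
classifier probability streams, and (4) centroid-distance evaluation plus
Nottingham grading. Each stage only removes candidates, so per-stage counts are
monotone non-increasing; the package logs them per image because the stages'
value is exactly that accounting (detector recall, cascade precision gain,
fusion precision gain).

## Detection geometry

Boxes are half-open pixel rectangles `[x_min, x_max) × [y_min, y_max)` with
0-based coordinates, `x` the column and `y` the row — one convention, stated
here, used everywhere. Box regression follows the standard anchor
parameterization: translations normalized by the anchor size,
`v_x = (x_p − x_a)/w_a`, `v_y = (y_p − y_a)/h_a`, and natural-log size ratios
`v_w = log(w_p/w_a)`, `v_h = log(h_p/h_a)`; decoding is the exact inverse and
round-trips to 1e-9 relative tolerance. Anchors are area-preserving: at scale
`s` and aspect ratio `r = h/w`, sides are `w = s/√r`, `h = s√r`, so area is
`s²` for every ratio. The default single scale is 64 px (mitotic nuclei are
small relative to the generic 128/256/512 detection scales) with ratios
1:2, 1:1, 2:1.

The detection loss is `L = L_cls(p, p*) + σ·p*·L_reg(v, v*)` with binary
cross-entropy for `L_cls` (probabilities clamped at 1e-12 so the log is
finite) and smooth-L1 summed over the four regression components for `L_reg`.
The source architecture names but never defines the two partial losses; these
are the standard choices of the detector family it builds on. The label gates
the regression term, so background anchors contribute classification loss
only.

NMS is greedy: keep the highest-scoring remaining detection, discard
neighbors with IoU strictly above the threshold; equal scores break by input
order, making the output deterministic. The proposal stage uses IoU 0.8; the
output stage default is 0.3 (the source leaves the output-stage value
unstated; both are configurable).

A trained deep detector is deliberately out of scope. The pipeline instead
defines a scorer-interface contract — any callable producing scored
`Detection` candidates plugs in — and ships a deterministic reference
detector: pixels darker than a gray threshold (ITU-R 601 luma < 180 by
default) are grouped into connected components; components of plausible
nuclear area (20–4000 px²) become candidates boxed at 48 px around their
centroid, scored by darkness × (0.5 + 0.5·size saturation), then suppressed at
IoU 0.3. It is a pure function of (image, config). Its job is candidate
recall, not discrimination — the downstream stages do the rejecting, exactly
as in the staged architecture it exercises.

## Tiling and augmentation

HPFs are larger than fixed-input models consume, so images are scanned with a
square window (default 521 px) on a stride grid. The dense 40-px stride is
the training-set extraction setting (with `keep_rule=with_annotation`
retaining only annotation-bearing patches, since fixed-size training inputs
are wanted); the inference scan uses stride 473 — one candidate-box width of
overlap — so nuclei straddling seams are seen whole, with the global NMS pass
removing the duplicates. No boundary-clipped patches are produced.
Annotations transfer to patch-local coordinates by subtraction and
detections map back by the inverse offset.

Augmentation transforms pixels and annotation coordinates together: hflip
maps `x → W−1−x`, vflip `y → H−1−y` (both involutions, tested as such),
translation fills uncovered pixels with the patch mean color (a dark constant
fill would manufacture fake candidates for the darkness-based detector), and
crop-resize rescales coordinates proportionally.

## Handcrafted features

Four families per candidate patch:

* **First-order statistics** — population mean, standard deviation, skewness
  `E[(x−μ)³]/σ³` and kurtosis `E[(x−μ)⁴]/σ⁴` of the gray patch. Kurtosis is
  uncorrected (normal ⇒ 3). A constant patch has undefined shape moments;
  they are reported as 0 with a `degenerate` flag.
* **LBP** (radius 1, 8 neighbors) — per interior pixel,
  `code = Σ s(g_i − g_c)·2^i` with `s(x) = 1` iff `x ≥ 0`, neighbors
  enumerated clockwise from the top-left neighbor; 256-bin histogram
  normalized to sum 1. `s(0) = 1` forces a constant patch to code 255
  everywhere. Plain 256-code LBP, not the uniform/rotation-invariant
  variants.
* **HOG** — patch resized to 64 × 128 (the 1:2 canonical geometry), gradients
  by the `[−1, 0, 1]` kernel (one-sided at borders), magnitude voted into 9
  unsigned orientation bins per 8 × 8 cell with hard assignment, 2 × 2-cell
  blocks sliding by one cell, each 36-vector L2-normalized (zero blocks left
  zero): 7 · 15 · 36 = 3780 values. Hard binning (no bilinear orientation
  interpolation) keeps the descriptor exactly reproducible by a naive oracle.
* **Color histograms** — 16 equal-width bins per 8-bit RGB channel over
  [0, 255], each channel normalized, concatenated R‖G‖B (48 values).

Grayscale everywhere is ITU-R 601 luma. LBP, central moments and HOG are
invariant to additive gray shifts (property-tested), which is why they
complement the intensity-sensitive color/mean features rather than duplicate
them.

## The threshold cascade

Each cascade stage thresholds one scalar "feature value" per candidate.
Vector families need a scalarization; the package uses similarity to the
mitotic-class template (the mean feature vector of mitotic training
candidates): cosine similarity for the stats 4-vector and HOG, histogram
intersection `Σ min(h_i, t_i)` for LBP and color. This preserves the
"resembles a mitosis" semantics of thresholding a feature value. Stage order
defaults to stats → LBP → HOG → color.

Calibration is sequential: each stage sees only the survivors of earlier
stages, picks the accept direction by comparing class means, and sets its
threshold to retain a configured fraction (default 0.99) of surviving mitotic
candidates. The threshold is not placed exactly on the retention-quantile
score: with retention 1.0 that is the minimum positive, and a held-out
positive then fails the stage whenever it lands below the training minimum
(probability ≈ 1/(n+1) per stage, compounding across four stages). Instead
the threshold sits at the midpoint of the gap between the quantile anchor and
the nearest negative on the reject side (anchor minus three positive-score
standard deviations when no negative lies there). Training retention is
unchanged; the held-out retention improves materially at realistic positive
counts (tens of mitoses per training set). An F1-maximizing grid mode is
available for users who prefer precision over the recall-first default.

Appending a stage can only shrink the accepted set (tested as a monotonicity
property), and rejected candidates carry the index of the first failing stage
for the per-stage accounting.

## Score-level fusion

Two independent scorers produce probabilities `(s_a, s_b)` per candidate. The
shipped reference is a pair of standardized logistic regressions over
complementary feature families (stats + color vs LBP + HOG); deep
convolutional scorers satisfy the same interface but are out of scope. The
decision is a three-stage hierarchy with strict comparisons:
`s_a > τ_a`, then `s_b > τ_b`, then `fused > τ_fused`, mitotic iff all pass;
ties reject. The fused score defaults to the equal-weight arithmetic mean
(the minimal combiner consistent with "fuse the two probabilistic scores"; a
weighted product rule is available). The decision is monotone in both scores.

Thresholds are calibrated by exhaustive grid search at step 0.01 over all
three thresholds, maximizing F1 of the hierarchical decision (or maximizing
F1 subject to a recall floor in `recall_retention` mode). Ties break toward
lower thresholds in (τ_a, τ_b, τ_fused) order, so calibration is
deterministic and invariant to shuffling the training list. Because single-
score rules are embedded in the grid (set the other two thresholds to 0),
the fused training F1 can never fall below the best single-score threshold
rule — the formal version of the claim that fusion does not hurt.

## Evaluation and grading

A detection is a true positive when its centroid lies strictly less than the
criterion distance from an unmatched ground-truth centroid: 20 px for the
2012-contest convention (5 µm at 0.2456 µm/px) and 32 px for the 2014
convention (8 µm). Matching is greedy nearest-first and one-to-one —
deterministic, and equal to the optimal assignment whenever each detection is
admissible for at most one truth (the separated regime the tests verify);
the contests define only the distance, not the assignment rule. Region-pixel
ground truth is reduced to the arithmetic-mean centroid before matching.
Precision, recall and F1 follow the usual definitions with 0/0 reported as 0
plus a degenerate flag. The Nottingham mitotic score sums ten per-field
counts: 0–9 → 1, 10–19 → 2, ≥ 20 → 3; exactly ten fields are required unless
the caller overrides.

## Synthetic data

The generator emulates the structure of an HPF, not its appearance: a noisy
pink background, anti-aliased elliptical blobs with random orientation and
eccentricity, per-blob colors drawn from class distributions (mitotic
dark blue-purple ≈ (62, 48, 118) ± 8; non-mitotic lighter purple
≈ (150, 120, 185) ± 8), per-pixel speckle (SD 6), pairwise blob separation
≥ 40 px, and exact planted centroids as ground truth. Defaults are full-HPF
scale (2084 px, 4 mitotic + 120 non-mitotic blobs — a realistic burden of a
high-grade case); the test suite and demos use 512-px scenes with 4 + 20
blobs to keep runtimes in seconds. A single `margin` knob pulls the
non-mitotic color distribution toward the mitotic one (1 = well separated,
0 = identical), which is how the calibration-recovery tests dial difficulty.
Ellipses exercise the shape/texture features without modeling real mitosis
morphology; the generator deliberately omits stain variation, scanner noise,
overlapping nuclei and apoptotic mimics — passing tests therefore demonstrate
the pipeline's mechanics and calibration behavior, not clinical performance.

The score simulator draws correlated bivariate-normal score pairs per class,
clipped to [0, 1] (defaults: positives (0.82, 0.78), negatives (0.20, 0.26),
SD 0.10, correlation 0.3, 1000 per class), for exercising fusion in
isolation. All generator outputs are bit-exact reproducible from
(config, seed).

## Numerical and degenerate-input choices

* Probability clamp 1e-12 in the log loss; box validity requires strictly
  positive sides; non-finite regression vectors are rejected at construction.
* NMS and matching ties break by input order / index order — determinism over
  elegance.
* All-zero HOG blocks are left zero rather than normalized; empty patches,
  single-class calibration inputs, and negative counts raise typed errors
  (`ConfigError` → CLI exit 2, `DataError` → exit 3).
* Detector boxes are clamped inside the image while keeping their size;
  patch-to-global mapping clips spilling boxes with a logged warning.

## Problem sizes used in tests and acceptance

End-to-end checks calibrate on 5 scenes and evaluate on 10 scenes of 512 px
(4 mitotic + 20 non-mitotic blobs each, margin 1.0, fixed seeds), reaching
F1 ≈ 0.99 against planted centroids at the 20-px criterion. Calibration
recovery uses 2000 synthetic candidates (cascade) and 2000 score pairs
(fusion). Oracle-equivalence suites use ≤ 25 boxes, 8 × 8 patches and 1000
score pairs, mirroring the scale at which the brute-force oracles are exact
and fast.

## Known limitations

* The reference detector keys on darkness; it will miss pale mitotic figures
  and cannot rank subtle texture differences — by design, trained scorers are
  the replaceable component.
* Template-similarity scalarization assumes a unimodal mitotic class per
  feature family; the four mitosis phases in real tissue are multimodal.
* Greedy matching can differ from optimal assignment in dense detection
  clusters (within-criterion chains); contest-style data with sparse mitoses
  rarely exhibits this.
* The synthetic scenes are far easier than H&E tissue; reported synthetic F1
  values say nothing about performance on clinical datasets.
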