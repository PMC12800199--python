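# Methods

`fundusdr` implements a complete desk-scale pipeline for five-level diabetic
retinopathy (DR) grading from color fundus photographs: image enhancement,
handcrafted feature extraction, deep-embedding fusion, and multi-class
classification with confusion-matrix metrics. Because real graded fundus
datasets are large and externally hosted, the package ships a synthetic
fundus generator with planted ground truth so every detector and the full
grading loop can be scored objectively without downloads.

## Synthetic fundus generator

`synth.generate_fundus` paints, on a near-black background:

* the bright circular retina disc (radius = `fundus_radius_frac` x half-side,
  default 0.9);
* an optic disc — a bright, near-saturated disc of radius 0.14 x fundus
  radius at 0.55 eccentricity and random azimuth;
* vessels as random quadratic Bézier strokes radiating from the optic disc
  toward the rim, with linearly tapering width (default 2–5 px at 512 px);
* small dark circular lesions (microaneurysm/hemorrhage analogues) and
  bright yellowish blobs (exudate analogues), placed by rejection sampling
  (at most 1000 attempts, then an error) so that no lesion overlaps another
  lesion, the optic disc, or a vessel — overlap would make the planted
  counts ambiguous as detection truth;
* a smooth multiplicative illumination field — a low-order 2-D polynomial
  rescaled into `illumination_gain_range` (default [0.6, 1.4]) — applied
  inside the fundus only, to exercise the enhancement pipelines' illumination
  correction;
* additive Gaussian sensor noise (`noise_sigma`, default 5 intensity units).

All randomness flows through one `numpy` generator seeded from the generation parameters, so
identical specs give byte-identical images. `generate_dataset` derives
per-image seeds deterministically from a master seed and assigns severity
grades 0–4 (No DR, Mild, Moderate, Severe, PDR) with lesion load increasing
with grade: grade *g* plants 3*g* dark lesions and 2*g* bright blobs. This
schedule makes grades separable but overlapping under noise — grade is
carried by lesion *count*, which the feature extractor must actually
estimate, not by any trivial global intensity cue.

What the generator does **not** emulate: photoreceptor texture, camera
optics and vignetting, resolution diversity, lesion sub-types with realistic
morphology (blot vs flame hemorrhages, hard vs soft exudates), and
inter-grader label noise. Passing tests therefore demonstrate that the
implementation is correct and self-consistent under controlled conditions —
not that the measured accuracies transfer to clinical images.

## Enhancement pipelines

All three methods keep intermediate arithmetic in floating point and
quantize to bytes only at the output, which keeps the contracts below exact.
Each stage has an on/off flag recorded in the output's `stage_trace`, so
per-stage ablations need no separate code path.

**ASE (adaptive sigmoid enhancement)** — grayscale conversion; CLAHE
(8x8 tiles, clip limit 2.0 in multiples of the uniform histogram height);
Gaussian smoothing (sigma 1 px); pixelwise sigmoid
`s(x) = 255 / (1 + exp(-g (x - c) / 255))` with gain g = 8 and center c
taken from the per-tile median, bilinearly resampled to full resolution;
additive blending of morphological top-hat (+0.5) and bottom-hat (−0.5)
maps with a 7-px disc element; final (1, 99) percentile stretch. The
sigmoid centered on the local median pushes locally-dark lesion pixels down
and background up, which is why the Michelson contrast between planted dark
lesions and their surrounding annulus rises (verified on seeded images).
With every optional stage disabled the method reduces exactly to grayscale
conversion.

**LAB-ACE** — the fundus mask is estimated, the image converted to LAB
(D65 white), CLAHE applied to the L channel, and the equalized L substituted
only inside the mask; a and b are untouched and every pixel outside the
mask is byte-identical to the input (enforced by copying input bytes, so
the contract holds exactly regardless of color round-trip error, which is
itself ≤ 2 byte levels).

**MIE (multi-channel enhancement)** — channels separated; green gain 1.2
(the green channel carries the strongest vessel/lesion contrast); per-channel
(1, 99) percentile stretch computed over the masked pixels, mapping the low
anchor to 0 and the high anchor to 255 exactly; recombination; gamma 0.9;
outside-mask pixels set to black. Whether the final adjustment should be a
gamma or another stretch was an open choice; gamma was selected and is
flagged in the parameter record.

**Fundus mask** — Otsu threshold on the red channel (brightest over the
retina), largest connected component, hole filling, largest inscribed circle
via Euclidean distance transform. A uniformly black image raises an
empty-mask error; a saturated frame yields a full mask.

## Handcrafted features

All extractors run on a standardized square resize (default 512 px for real
images; the synthetic pipeline uses 128 px with detector parameters scaled
accordingly), so fragment lengths are input-size independent.

The 90-dimensional custom vector (`CUSTOM90`) is laid out as:

| block | features |
|---|---|
| LBP uniform histogram, radius 1 / 8 points | 10 |
| LBP uniform histogram, radius 2 / 16 points | 18 |
| 12 Haralick statistics of the symmetric normalized GLCM (32 levels), averaged over offsets (0,1), (1,0), (1,1), (1,−1) | 12 |
| Gabor bank: 3 frequencies x 4 orientations x (mean, std of response magnitude) | 24 |
| lesion block: circle count, mean circle radius, mean circle score, exudate area fraction, vessel area fraction | 5 |
| per-channel (R, G, B) masked intensity statistics: mean, population variance, skewness, kurtosis, median, byte mode (smallest on tie), std | 21 |

The 12 GLCM statistics are contrast, correlation, energy, homogeneity,
entropy, dissimilarity, ASM, cluster shade, cluster prominence, maximum
probability, sum average, and difference variance. Degenerate conventions:
correlation of a single-level matrix is 1; skewness/kurtosis of a constant
distribution are 0.

Two further fixed sets mirror the common comparison-table groupings:
`HOG_LBP_BASIC` (pooled 36-dim HOG + LBP(1,8) + 7 grayscale intensity
statistics + 4 edge features = 57) and `GLCM_HARALICK` (12 statistics x 4
offsets unaveraged = 48). "Basic features" are mapped to intensity + edge
statistics; the grouping is configuration-visible since no canonical
itemization exists.

**Circle detection.** Canny edges of the inverted green channel vote in a
circular Hough accumulator over the configured radius range. Raw peak
thresholding is insufficient at small radii — a vessel arc produces
normalized accumulator peaks as strong as a genuine radius-4 lesion — so
each candidate is validated as blob-like: relative to the midpoint of the
interior and annulus means, at least 60% of the circle interior must be
dark while at most 10% of the surrounding annulus is. A vessel fails this
because it continues through the annulus. Survivors undergo non-maximum
suppression within one radius. With the default sensitivity of 0.6 the
detector recovers 4/4 planted circles within 2 px on 20/20 noiseless seeds
with zero false positives on lesion-free images (planted true circles score
≥ 0.67, the strongest observed spurious peak 0.54).

**Exudate area.** Otsu threshold on the masked green channel plus a fixed
offset (default +20), morphological opening (1-px disc) then closing
(2-px disc). The optic disc is excluded by dropping *every* bright
component touching the top-0.1% brightest pixels — vessels crossing the
disc split it into several components, each carrying near-saturated pixels,
so removing only the largest would leave fragments counted as exudate.

**Vessel area.** Morphological bottom-hat on the green channel with a disc
element wider than the thickest vessel, Otsu-thresholded (floored at 8
intensity units), speck components removed. Returns the masked pixel count
and the binary map.

## Deep features and fusion

The deep embedding contract is the penultimate-layer activation vector of a
pretrained backbone applied to the *enhanced* image. The default backbone
is a deterministic stub: grayscale 32x32 downsample, flatten, a fixed
seeded Gaussian random projection (scaled 1/sqrt(1024)) to 128 dimensions,
and rectification. It requires no weights or network and exercises every
downstream stage exactly as a real network would; distinct images map to
distinct embeddings with overwhelming probability. ResNet-50 (global-pooled
2048-vector before the classification head) is available behind the optional
`torch` extra; "penultimate fully connected layer" is interpreted as this
pre-classification vector, since the architecture has a pooling stage there
rather than a second FC layer.

Fusion is feature-level concatenation, handcrafted first, names prefixed by
origin (90 + 128 = 218 dimensions with the defaults).

## Splitting, classifiers, metrics

The 70:30 split is stratified by default: each class is shuffled with the
seeded generator and `floor(0.7 n)` samples go to train. Classifiers are
SVM (RBF, C = 1, gamma = 1/d), KNN (k = 5, Euclidean), random forest (300
trees) and XGBoost (300 rounds, depth 6, learning rate 0.1, L1 = 0, L2 = 1);
features are standardized to train-set mean/std for the scale-sensitive SVM
and KNN only.

Evaluation builds the full 5x5 confusion matrix (absent classes appear as
zero rows) and derives one-vs-rest TP/FP/FN/TN per class. Precision, recall
and F1 use the 0-convention on empty denominators. Macro precision and
recall are unweighted class means. Two macro-F1 conventions are reported,
because both appear in published comparison tables and they differ in the
fourth decimal on some rows: `macro_f1_hm` = harmonic mean of macro
precision and macro recall, and `macro_f1_avg` = unweighted mean of
per-class F1.

## Problem sizes and numerical choices

The stochastic end-to-end properties (5-class accuracy well above the 0.20
chance level; fusion never substantially hurting) are measured at 60 images
per grade, 128-px images, over 3 master seeds — sizes chosen so the whole
suite runs comfortably on a laptop while leaving the accuracy margin wide
(measured fused XGBoost accuracy ≈ 0.9 versus the 0.60 bar). Seeds derive
from a single master seed through one `numpy` generator and stay below
2^31. Feature tables round-trip through CSV losslessly (17 significant
digits on write, exact float parsing on read).

## Known limitations

* The synthetic generator's flat-color structures are far easier to enhance
  and segment than real retinas; absolute accuracies here say nothing about
  clinical performance.
* The exudate optic-disc exclusion assumes the disc outshines every
  exudate; on images where it does not, bright lesions touching the
  intensity ceiling would be discarded.
* The circle detector's blob validation assumes roughly uniform lesion
  interiors; ring-shaped or partially occluded lesions would be rejected.
* The stub backbone is a fixed random projection: it preserves coarse
  spatial intensity information but learns nothing, so fusion gains over
  handcrafted features alone are modest by design.
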