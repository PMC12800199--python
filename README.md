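# fundusdr

Diabetic retinopathy (DR) grading toolkit: fundus-image enhancement,
handcrafted + deep feature fusion, and five-level severity classification —
with a built-in synthetic fundus generator so every stage can be developed
and scored without downloading clinical data.

DR is graded from color fundus photographs into five severity levels
(0 No DR, 1 Mild, 2 Moderate, 3 Severe, 4 PDR) based on lesion load:
microaneurysms and hemorrhages appear as small dark circular spots,
exudates as bright yellowish blobs. The package implements the classic
hybrid recipe for this problem:

1. **Enhancement** — three pipelines with per-stage ablation flags:
   *ASE* (CLAHE + locally-centered sigmoid contrast + top-hat/bottom-hat
   blending), *LAB-ACE* (CLAHE on the LAB lightness channel, chromatics and
   everything outside the fundus untouched), and *MIE* (green-channel gain +
   per-channel masked percentile stretch + gamma).
2. **Handcrafted features** — a fixed, named 90-dimensional vector: LBP
   histograms (radius 1 and 2), 12 Haralick/GLCM statistics, a Gabor filter
   bank, a lesion block (Hough circle count/radius/score, exudate and vessel
   area fractions), and per-channel intensity statistics.
3. **Deep features** — the penultimate-layer embedding of a pluggable
   backbone; a deterministic offline stub (128-dim seeded random projection)
   is the default, ResNet-50 an optional `torch` extra.
4. **Fusion + grading** — feature-level concatenation, stratified 70:30
   split, SVM / KNN / random forest / XGBoost, and confusion-matrix metrics:
   accuracy, per-class and macro precision/recall, and both macro-F1
   conventions (harmonic mean of macro P and R, and mean of per-class F1,
   F1 = 2PR/(P+R)).

The synthetic generator plants vessels, dark lesions and bright blobs with
recorded ground truth, applies a smooth multiplicative illumination field
and sensor noise, and labels images by a lesion-load schedule (grade *g* →
3*g* dark + 2*g* bright lesions), so detectors are scored against known
truth. See `docs/methods.md` for the full model description and its limits.

## Worked example

```python
from fundusdr import (RunConfig, run_pipeline)

cfg = RunConfig(seed=0)          # 128-px synthetic desk scale
cfg.synth.n_per_class = 60       # 300 labelled images, 5 grades
result = run_pipeline(cfg)
print(round(result["accuracy"], 3), round(result["macro"]["f1_hm"], 3))
```

prints

```
0.911 0.912
```

i.e. fused (90 handcrafted + 128 stub-deep) features with XGBoost grade the
held-out 30% of a 300-image synthetic set at 91.1% accuracy (chance is 20%),
with macro-F1 0.912. Lower-level entry points are exposed per stage:

```python
from fundusdr import SyntheticSpec, generate_fundus, enhance, extract_handcrafted

img, truth = generate_fundus(SyntheticSpec(image_size=512, n_dark_lesions=6, seed=1))
enhanced = enhance(img, "ase")                  # or "labace", "mie"
fv = extract_handcrafted(enhanced, "CUSTOM90")  # 90 named features
```

The same stages are available from the shell via the `fundusdr` command
(`synth`, `enhance`, `features`, `deep-features`, `train`, `pipeline`,
`report`); every run is reproducible from its config file and master seed,
and outputs embed the config hash.

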