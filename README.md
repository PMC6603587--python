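# csvd

Computer-aided detection of cerebral small-vessel lesions on 2D brain-MRI
slices: rule-based brain extraction, 7×7 patch-based 4-class classification
with a small CNN (NumPy, CPU-only), reassembly into labeled segmentation
maps, lesion localization / area / stacked-3D reporting, rate-valued
confusion metrics, and a synthetic phantom generator so the whole pipeline
is testable without clinical data.

## Pipeline

1. **Brain extraction** (`csvd.brain_extraction`) — binarize (Otsu or fixed
   threshold), remove the largest connected component (the cranium ring),
   inverse-binarize, union restricted to intracranial components, median
   filter, then geometry (bbox / centroid / area).
2. **Patching** (`csvd.patching`) — non-overlapping 7×7 tiling with
   bottom/right zero padding; ground-truth patch labels via `any_lesion`
   (class 3 wins if one lesion pixel is present) or `majority_priority`.
3. **Classifier** (`csvd.classifier`) — a 7-layer CNN
   (conv16 → conv32 → pool2 → conv64 → fc128 → fc64 → fc4 + softmax) and an
   MLP baseline (49 → 128 → 64 → 4), trained with seeded SGD + momentum on
   cross-entropy; fully deterministic given the seed.
4. **Metrics** (`csvd.metrics`) — 2×2 lesion/non-lesion confusion tables with
   exact *fractional* entries (e.g. TP = 94/95) and the evaluation formulas
   applied to those rates: precision = TP/(TP+FP), as-printed recall =
   FN/(TP+FN) (the miss rate; textbook sensitivity is provided as
   `standard_recall`), F1 = harmonic mean.  `reproduce_report_tables()`
   recomputes the published summary tables cell-for-cell at 9 decimals.
5. **Lesion report** (`csvd.lesion_report`) — per-slice lesion records
   (centroid, bbox, area in px/mm², max diameter, <1.5 cm small-vessel flag)
   and 26-connected stacking across slices into 3D groups with volumes
   (inter-slice spacing defaults to 3.4 mm thickness + 1 mm gap = 4.4 mm).
6. **Phantom** (`csvd.phantom`) — seeded synthetic slices (bright cranium
   ring, brain disk, central ellipse, 0–4 hyperintense sub-1.5 cm lesions,
   Gaussian noise) with exact paired label maps and a stratified
   train/val/test split in 205/205/206 proportions.

Label classes: 0 non-brain (black), 1 normal brain (green), 2 central brain
(blue), 3 lesion (red).  Coordinates are 0-based (row, col), row 0 at the
top.  I/O: PNG/TIFF grayscale, RGB-PNG label maps, and single-frame
grayscale DICOM (minimal built-in reader/writer).

## CLI

```sh
csvd simulate --n 200 --seed 7 --size 64 --out data/
csvd preprocess --in data/ --out pre/ --threshold otsu --median 3
csvd patchify --in data/ --out patches.csv --rule any_lesion
csvd train --data data/ --kind cnn --epochs 180 --seed 42 --out model.npz
csvd predict --model model.npz --in data/slice_0000.png --out pred_0000.png
csvd evaluate --pred preds/ --truth data/ --unit patch --out metrics.json
csvd report --pred preds/ --spacing 0.5 --out report.json
csvd reproduce-tables         # recompute the published summary tables
csvd run --n 30 --size 64 --epochs 20 --seed 7 --out out/   # end to end
```

Exit codes: 0 ok, 2 config, 3 I/O, 4 degenerate input, 5 reproduction
mismatch.

## Notes

- Everything runs on one CPU with NumPy/SciPy/scikit-image only; no deep
  learning framework is required.
- In-plane pixel spacing is never inferred from image content; mm-valued
  outputs require explicit spacing (CLI default 0.5 mm/px, documented as an
  assumption).
- The <1.5 cm small-vessel criterion is reported as a flag, never used to
  suppress detections.
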