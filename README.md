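# lentil-eye

Seed phenotyping from uncalibrated photographs. Given an RGB image of
seeds scattered on a dark surface with a 1 mm graph-paper strip in
frame, the pipeline:

1. **detects each seed as a circle** with a randomized three-point
   circumcircle detector on an adaptive Canny edge map, screened by a
   per-image radius statistic (mean ± 2 SD) and a radiometric check
   (circles with more than 10% dark background pixels inside are
   discarded);
2. **calibrates the scale** by finding the graph-paper squares as
   4-vertex contour polygons, taking the modal side length in pixels
   (EDV) against the known 1 mm side (ADV), so S = ADV/EDV converts the
   mean detected radius to a seed diameter in millimetres;
3. **classifies each seed's testa pattern** in two steps: a
   gradient-boosted tree ensemble maps a 198-dim descriptor
   (18-bin rotation-invariant uniform LBP + 60-bin-per-channel RGB
   histograms) to a texture group (rare / sparse / dense), then a
   morphological region analysis (adaptive Canny → closing → contour
   following → area) refines the group into the five canonical classes:
   rare → absent or spotted, sparse → dotted or complex (more than half
   the surface covered), dense → marbled.

A synthetic-scene module renders seed scenes and labeled single-seed
patches with exact ground truth, so the whole pipeline is testable
without any photographic dataset.

## CLI

```sh
lentil-eye simulate --n-scenes 3 --seeds-per-scene 10 --px-per-mm 20 --seed 0 --out scenes/
lentil-eye detect scenes/scene_000.png --out circles.csv
lentil-eye calibrate scenes/scene_000.png            # prints {"EDV":..., "S":..., "n_squares":...}
lentil-eye features patches/ --out features.csv
lentil-eye train features.csv labels.csv --out model.bin
lentil-eye evaluate features.csv labels.csv --kfold 10
lentil-eye classify scenes/scene_000.png --model model.bin --out seeds.csv
lentil-eye run manifest.csv --model model.bin --out report.json
lentil-eye metrics --confusion cm.csv --sizes sizes.csv
```

`manifest.csv` needs an `image_path` column and optionally
`measured_size_mm` for size-error statistics. Detector, subclass and
calibration parameters live in one YAML config (`--config`); see
`lentil_eye.cli_pipeline.PipelineConfig`.

Note on units: the reported seed "size" is the **diameter** in mm
(2 × mean radius / EDV).

## Layout

```
src/lentil_eye/
  synthetic_scene.py   scene/patch generators with ground truth
  circle_detect.py     edge map, randomized circle detection, screens, patches
  scale_calib.py       square detection, EDV/S estimation, mm conversion
  texture_features.py  18-bin LBP + 180-bin color histogram descriptors
  texture_classify.py  boosted-tree texture-group classifier + CV protocols
  pattern_subclass.py  morphological region analysis + 5-class rules
  metrics.py           confusion matrices, accuracies, F1, size errors
  cli_pipeline.py      per-image / per-dataset orchestration
  cli.py               the lentil-eye command
tests/                 unit, property and acceptance suites
scripts/acceptance.py  acceptance report generator
```
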